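"""Trikinetics DAM monitor file I/O, validation, and Zeitgeber alignment.

The Drosophila Activity Monitor (DAM) records infrared beam breaks for
32 flies in 1-minute bins.  A data line in the DAM2 dialect is
tab-delimited with 42 fields: a running index, the date (``DD Mon YY``),
the time (``HH:MM:SS``), a monitor status code, six device fields (kept
verbatim, never interpreted), and 32 integer channel counts.

Light state is always derived from a declared :class:`LightSchedule`
(the experimental protocol), never from the monitor's light sensor, so
LD and DD analyses are driven by design rather than hardware noise.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import io
from pathlib import Path

import numpy as np
import pandas as pd

N_CHANNELS = 32
MINUTES_PER_DAY = 1440
#: DAM2 status code for a valid reading.
STATUS_VALID = 1

AGE_CLASSES = ("young", "mature")

DESIGN_COLUMNS = ["monitor", "channel", "genotype", "age_class", "include"]


class DamIOError(ValueError):
    """Base class for DAM ingestion failures."""


class MalformedFileError(DamIOError):
    """A line does not have the expected 42 tab-separated fields."""


class DamParseError(DamIOError):
    """A field could not be parsed (bad integer, bad date)."""


class AlignmentError(DamIOError):
    """Timestamps are not strictly increasing at 1-minute spacing."""


class InsufficientDataError(AlignmentError):
    """The recording does not span a full ZT0-to-ZT0 day."""


class UnsupportedWidthError(DamIOError):
    """More channels than the 32 the DAM2 dialect can carry."""


_MONTH_NUM = {
    "Jan": 1, "Feb": 2, "Mar": 3, "Apr": 4, "May": 5, "Jun": 6,
    "Jul": 7, "Aug": 8, "Sep": 9, "Oct": 10, "Nov": 11, "Dec": 12,
}
_MONTH_ABBR = {v: k for k, v in _MONTH_NUM.items()}


def _parse_timestamp(date_field: str, time_field: str) -> dt.datetime:
    # Month names are mapped explicitly so parsing is locale-independent.
    day_s, mon_s, year_s = date_field.split()
    hh, mm, ss = time_field.split(":")
    return dt.datetime(
        2000 + int(year_s), _MONTH_NUM[mon_s], int(day_s),
        int(hh), int(mm), int(ss),
    )


def _format_timestamp(ts: pd.Timestamp) -> tuple[str, str]:
    date_field = f"{ts.day} {_MONTH_ABBR[ts.month]} {ts.year % 100:02d}"
    time_field = f"{ts.hour:02d}:{ts.minute:02d}:{ts.second:02d}"
    return date_field, time_field


@dataclasses.dataclass
class LightSchedule:
    """Declared lighting protocol defining Zeitgeber time.

    Parameters
    ----------
    lights_on : datetime.time
        Clock time of lights-on; defines ZT0.
    photoperiod_hours : float
        Hours of light per cycle (12 for LD 12:12).
    regime : str
        ``"LD"`` (light-dark cycling) or ``"DD"`` (constant darkness),
        applied to every experimental day unless ``regime_by_day``
        overrides it.
    regime_by_day : dict[int, str], optional
        Per-day regime overrides keyed by day index (0-based, counted
        from the first aligned day).
    """

    lights_on: dt.time = dt.time(6, 0)
    photoperiod_hours: float = 12.0
    regime: str = "LD"
    regime_by_day: dict[int, str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.photoperiod_hours <= 24.0:
            raise ValueError("photoperiod_hours must be in [0, 24]")
        if self.regime not in ("LD", "DD"):
            raise ValueError("regime must be 'LD' or 'DD'")

    def zt_minutes(self, timestamps: pd.DatetimeIndex) -> np.ndarray:
        """Zeitgeber minute (0-1439) of each timestamp."""
        minute_of_day = (
            timestamps.hour * 60 + timestamps.minute
        ).to_numpy()
        on = self.lights_on.hour * 60 + self.lights_on.minute
        return (minute_of_day - on) % MINUTES_PER_DAY

    def regime_for_day(self, day: int) -> str:
        if self.regime_by_day is not None and day in self.regime_by_day:
            return self.regime_by_day[day]
        return self.regime

    def light_state(self, zt_minute: np.ndarray, day_index: np.ndarray) -> np.ndarray:
        """Boolean lights-on state from the declared protocol."""
        if len(day_index) == 0:
            return np.zeros(0, dtype=bool)
        day_is_ld = np.zeros(int(day_index.max()) + 1, dtype=bool)
        for d in np.unique(day_index):
            day_is_ld[int(d)] = self.regime_for_day(int(d)) == "LD"
        lit = zt_minute < self.photoperiod_hours * 60
        return lit & day_is_ld[day_index]


@dataclasses.dataclass
class ActivityMatrix:
    """Minute-resolution beam-break counts for up to 32 channels.

    ``counts`` has one row per minute and one column per channel.
    ``meta`` holds the six verbatim device fields per row for lossless
    round trips; ``zt_minute``/``day_index``/``light_state`` are filled
    by :func:`align_to_zt`.
    """

    timestamps: pd.DatetimeIndex
    counts: np.ndarray
    status: np.ndarray
    meta: list[tuple[str, ...]] | None = None
    light_state: np.ndarray | None = None
    zt_minute: np.ndarray | None = None
    day_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise DamIOError("counts must be 2-D (minutes x channels)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise DamParseError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise DamIOError("counts must be non-negative")
        self.status = np.asarray(self.status, dtype=np.int64)
        if len(self.timestamps) != self.counts.shape[0]:
            raise DamIOError("timestamps and counts disagree in length")
        if len(self.status) != self.counts.shape[0]:
            raise DamIOError("status and counts disagree in length")
        _check_minute_spacing(self.timestamps)

    @property
    def n_minutes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_channels(self) -> int:
        return self.counts.shape[1]

    @property
    def valid(self) -> np.ndarray:
        """Per-row boolean: monitor status marks the reading valid."""
        return self.status == STATUS_VALID

    def _slice(self, i: int, j: int) -> "ActivityMatrix":
        return ActivityMatrix(
            timestamps=self.timestamps[i:j],
            counts=self.counts[i:j].copy(),
            status=self.status[i:j].copy(),
            meta=None if self.meta is None else self.meta[i:j],
        )


def _check_minute_spacing(timestamps: pd.DatetimeIndex) -> None:
    if len(timestamps) < 2:
        return
    deltas = np.diff(timestamps.asi8)
    one_min = 60 * 10**9
    bad = np.flatnonzero(deltas != one_min)
    if len(bad):
        i = int(bad[0])
        raise AlignmentError(
            f"timestamps are not strictly increasing at 1-min spacing "
            f"between rows {i} and {i + 1} "
            f"({timestamps[i]} -> {timestamps[i + 1]})"
        )


def make_timestamps(start: dt.datetime, n_minutes: int) -> pd.DatetimeIndex:
    """A 1-minute DatetimeIndex of length ``n_minutes`` from ``start``."""
    return pd.date_range(start=start, periods=n_minutes, freq="min")


def read_dam_file(path: str | Path) -> ActivityMatrix:
    """Parse a DAM2-dialect monitor file.

    Rows with an invalid status code are retained but flagged (see
    :attr:`ActivityMatrix.valid`); downstream sleep scoring treats them
    as missing minutes.
    """
    timestamps: list[dt.datetime] = []
    status: list[int] = []
    counts: list[list[int]] = []
    meta: list[tuple[str, ...]] = []
    path = Path(path)
    with open(path, "r", encoding="ascii") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 10 + N_CHANNELS:
                raise MalformedFileError(
                    f"{path.name}: line {lineno}: expected {10 + N_CHANNELS} "
                    f"tab-separated fields, got {len(fields)}"
                )
            try:
                ts = _parse_timestamp(fields[1], fields[2])
                st = int(fields[3])
                row = [int(x) for x in fields[10:]]
            except (ValueError, KeyError) as exc:
                raise DamParseError(
                    f"{path.name}: line {lineno}: {exc}"
                ) from exc
            if any(c < 0 for c in row):
                raise DamParseError(
                    f"{path.name}: line {lineno}: negative count"
                )
            timestamps.append(ts)
            status.append(st)
            counts.append(row)
            meta.append(tuple(fields[4:10]))
    arr = (
        np.array(counts, dtype=np.int64)
        if counts
        else np.zeros((0, N_CHANNELS), dtype=np.int64)
    )
    return ActivityMatrix(
        timestamps=pd.DatetimeIndex(timestamps),
        counts=arr,
        status=np.array(status, dtype=np.int64),
        meta=meta,
    )


def write_dam_file(m: ActivityMatrix, path: str | Path) -> None:
    """Emit a DAM2-dialect file; ``read_dam_file`` round-trips it exactly.

    Matrices with fewer than 32 channels are zero-padded on write (the
    dialect always carries 32 count fields).
    """
    if m.n_channels > N_CHANNELS:
        raise UnsupportedWidthError(
            f"cannot write {m.n_channels} channels; DAM2 carries {N_CHANNELS}"
        )
    buf = io.StringIO()
    pad = [0] * (N_CHANNELS - m.n_channels)
    for i in range(m.n_minutes):
        date_field, time_field = _format_timestamp(m.timestamps[i])
        device = m.meta[i] if m.meta is not None else ("1",) * 6
        fields = [
            str(i + 1), date_field, time_field, str(int(m.status[i])),
            *device,
            *[str(int(c)) for c in m.counts[i]],
            *[str(c) for c in pad],
        ]
        buf.write("\t".join(fields) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="ascii")


def align_to_zt(m: ActivityMatrix, schedule: LightSchedule) -> ActivityMatrix:
    """Trim a recording to whole ZT0-to-ZT0 days and annotate ZT/day.

    The output starts at the first ZT0 *strictly after* the recording
    start: a recording that begins exactly at ZT0 discards its first
    day, which keeps the post-loading acclimation period out of every
    analysis.  Output length is always a multiple of 1440 minutes and
    the first row has ZT 0.
    """
    if m.n_minutes == 0:
        raise InsufficientDataError("empty recording")
    zt = schedule.zt_minutes(m.timestamps)
    starts = np.flatnonzero(zt == 0)
    starts = starts[starts > 0]
    if len(starts) == 0:
        raise InsufficientDataError(
            "recording never reaches a ZT0 after its start"
        )
    first = int(starts[0])
    n_days = (m.n_minutes - first) // MINUTES_PER_DAY
    if n_days < 1:
        raise InsufficientDataError(
            f"only {m.n_minutes - first} minutes after the first ZT0; "
            f"a full {MINUTES_PER_DAY}-min day is required"
        )
    out = m._slice(first, first + n_days * MINUTES_PER_DAY)
    out.zt_minute = np.arange(out.n_minutes) % MINUTES_PER_DAY
    out.day_index = np.arange(out.n_minutes) // MINUTES_PER_DAY
    out.light_state = schedule.light_state(out.zt_minute, out.day_index)
    return out


# ---------------------------------------------------------------------------
# Experiment design tables


def fly_id(monitor: str, channel: int) -> str:
    """Canonical fly identifier ``monitor:channel`` (channel 1-based)."""
    return f"{monitor}:{int(channel)}"


def validate_design(
    design: pd.DataFrame, age_classes: tuple[str, ...] = AGE_CLASSES
) -> pd.DataFrame:
    """Validate a channel-to-genotype design table and add a ``fly`` column."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise DamIOError(f"design table missing columns: {missing}")
    dup = design.duplicated(subset=["monitor", "channel"])
    if dup.any():
        rows = design.loc[dup, ["monitor", "channel"]].to_records(index=False)
        raise DamIOError(f"duplicate (monitor, channel) entries: {list(rows)}")
    bad = set(design["age_class"]) - set(age_classes)
    if bad:
        raise DamIOError(
            f"unknown age_class values {sorted(bad)}; expected {age_classes}"
        )
    design = design.copy()
    design["include"] = design["include"].astype(bool)
    design["fly"] = [
        fly_id(mon, ch) for mon, ch in zip(design["monitor"], design["channel"])
    ]
    return design


def read_design(path: str | Path) -> pd.DataFrame:
    """Read and validate a tab-delimited design table."""
    df = pd.read_csv(path, sep="\t")
    return validate_design(df)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design[DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Normalized per-fly minute tables (the ingest output consumed downstream)


def to_minute_table(m: ActivityMatrix, monitor: str) -> pd.DataFrame:
    """Wide per-fly minute table for one ZT-aligned monitor."""
    if m.zt_minute is None:
        raise DamIOError("matrix must be ZT-aligned first (align_to_zt)")
    data = {
        "zt_minute": m.zt_minute,
        "day_index": m.day_index,
        "light": m.light_state.astype(int),
        "valid": m.valid.astype(int),
    }
    for ch in range(m.n_channels):
        data[fly_id(monitor, ch + 1)] = m.counts[:, ch]
    return pd.DataFrame(data)


def merge_minute_tables(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Join per-monitor minute tables on the shared ZT/day columns."""
    base = tables[0]
    for t in tables[1:]:
        if len(t) != len(base):
            raise AlignmentError("monitors span different numbers of days")
        fly_cols = [c for c in t.columns if ":" in c]
        base = pd.concat([base, t[fly_cols]], axis=1)
    return base


def write_minute_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_minute_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def minute_table_flies(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if ":" in c]
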