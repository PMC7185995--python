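"""Sleep scoring from minute-bin activity and sleep-architecture metrics.

Fly sleep is operationally defined as five or more consecutive minutes
without beam-break activity.  Every maximal run of >= 5 zero-count
minutes is one sleep bout; runs of 1-4 zero minutes contribute no
sleep.  Scoring runs on the continuous recording so bouts spanning the
ZT0 midnight are preserved; each sleep minute is then assigned to its
own day, and a bout is *counted* once, in the phase (day/night) and day
of its onset.  Minutes of a bout spanning the ZT12 lights-off boundary
are split between day and night so that day + night sleep always sums
to total sleep.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .dam_io import MINUTES_PER_DAY, ActivityMatrix, fly_id

#: Minimum run of inactive minutes that counts as sleep.
MIN_BOUT_MINUTES = 5
#: ZT minute at which lights go off under LD 12:12.
DAY_MINUTES = 720


class SleepScoringError(ValueError):
    """Inconsistent inputs to sleep scoring."""


@dataclasses.dataclass(frozen=True)
class SleepBout:
    """One maximal run of consolidated inactivity.

    ``start`` is the minute index within the ZT-aligned recording, so
    ``start % 1440`` is the ZT minute of onset.
    """

    start: int
    duration: int
    phase_of_onset: str

    @property
    def end(self) -> int:
        return self.start + self.duration


@dataclasses.dataclass
class SleepSummary:
    """Per fly, per day sleep architecture."""

    fly: str
    day: int
    total_sleep: int
    day_sleep: int
    night_sleep: int
    day_bout_number: int
    night_bout_number: int
    day_bout_length_mean: float
    night_bout_length_mean: float
    #: False when the phase had zero bouts (its mean is reported as 0).
    day_mean_defined: bool = True
    night_mean_defined: bool = True


def _phase_of(minute_index: int) -> str:
    return "day" if (minute_index % MINUTES_PER_DAY) < DAY_MINUTES else "night"


def detect_sleep_bouts(
    counts: np.ndarray,
    missing: np.ndarray | None = None,
    min_bout: int = MIN_BOUT_MINUTES,
) -> list[SleepBout]:
    """Find every maximal run of >= ``min_bout`` zero-count minutes.

    ``missing`` flags minutes excluded from scoring (e.g. invalid
    monitor status); a run of zeros cannot bridge a missing minute, so
    gaps conservatively break bouts.  Only zero vs nonzero matters:
    there is no movement threshold or smoothing.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1:
        raise SleepScoringError("counts must be a 1-D minute series")
    if np.any(counts < 0):
        raise SleepScoringError("negative activity counts")
    inactive = counts == 0
    if missing is not None:
        missing = np.asarray(missing, dtype=bool)
        if missing.shape != counts.shape:
            raise SleepScoringError("missing mask shape mismatch")
        inactive = inactive & ~missing
    edges = np.diff(np.concatenate(([0], inactive.astype(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [
        SleepBout(int(s), int(e - s), _phase_of(int(s)))
        for s, e in zip(starts, ends)
        if e - s >= min_bout
    ]


def sleep_state(
    counts: np.ndarray,
    missing: np.ndarray | None = None,
    min_bout: int = MIN_BOUT_MINUTES,
) -> np.ndarray:
    """Boolean per-minute sleep indicator implied by the bout definition."""
    asleep = np.zeros(len(np.asarray(counts)), dtype=bool)
    for b in detect_sleep_bouts(counts, missing=missing, min_bout=min_bout):
        asleep[b.start : b.end] = True
    return asleep


def _overlap(bout: SleepBout, lo: int, hi: int) -> int:
    return max(0, min(bout.end, hi) - max(bout.start, lo))


def summarize_sleep(
    bouts: list[SleepBout], day: int, fly: str = "fly"
) -> SleepSummary:
    """Summarize one fly-day from bouts intersecting that day.

    Minutes are partitioned at the ZT12 boundary; a boundary-spanning
    bout contributes minutes to both phases but is counted once, in the
    phase of its onset.  Bout-length means are over bouts counted in the
    phase and use full bout durations.
    """
    day_start = day * MINUTES_PER_DAY
    day_end = day_start + MINUTES_PER_DAY
    noon = day_start + DAY_MINUTES
    day_sleep = night_sleep = 0
    day_lengths: list[int] = []
    night_lengths: list[int] = []
    for b in bouts:
        if _overlap(b, day_start, day_end) == 0:
            raise SleepScoringError(
                f"bout at minute {b.start} lies outside day {day}"
            )
        day_sleep += _overlap(b, day_start, noon)
        night_sleep += _overlap(b, noon, day_end)
        if day_start <= b.start < day_end:
            (day_lengths if b.phase_of_onset == "day" else night_lengths).append(
                b.duration
            )
    return SleepSummary(
        fly=fly,
        day=day,
        total_sleep=day_sleep + night_sleep,
        day_sleep=day_sleep,
        night_sleep=night_sleep,
        day_bout_number=len(day_lengths),
        night_bout_number=len(night_lengths),
        day_bout_length_mean=float(np.mean(day_lengths)) if day_lengths else 0.0,
        night_bout_length_mean=(
            float(np.mean(night_lengths)) if night_lengths else 0.0
        ),
        day_mean_defined=bool(day_lengths),
        night_mean_defined=bool(night_lengths),
    )


def score_fly(
    counts: np.ndarray,
    fly: str = "fly",
    missing: np.ndarray | None = None,
) -> list[SleepSummary]:
    """Score a ZT-aligned recording and summarize each complete day.

    The full recording is scored first so bouts spanning ZT0 are kept
    intact; their minutes are then assigned day by day.
    """
    counts = np.asarray(counts)
    n_days = len(counts) // MINUTES_PER_DAY
    bouts = detect_sleep_bouts(counts, missing=missing)
    out = []
    for d in range(n_days):
        lo, hi = d * MINUTES_PER_DAY, (d + 1) * MINUTES_PER_DAY
        todays = [b for b in bouts if _overlap(b, lo, hi) > 0]
        out.append(summarize_sleep(todays, d, fly=fly))
    return out


def summarize_matrix(
    m: ActivityMatrix,
    monitor: str,
    include: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-fly-day SleepSummary rows for a ZT-aligned monitor matrix.

    Invalid-status rows are treated as missing minutes for every fly.
    """
    if m.zt_minute is None:
        raise SleepScoringError("matrix must be ZT-aligned (align_to_zt)")
    missing = ~m.valid
    rows = []
    for ch in range(m.n_channels):
        if include is not None and not include[ch]:
            continue
        fid = fly_id(monitor, ch + 1)
        for s in score_fly(m.counts[:, ch], fly=fid, missing=missing):
            rows.append(dataclasses.asdict(s))
    return pd.DataFrame(rows)


def summarize_monitors(monitors, schedule) -> pd.DataFrame:
    """ZT-align and score every monitor; concatenated per-fly-day rows."""
    from .dam_io import align_to_zt

    frames = [
        summarize_matrix(align_to_zt(m, schedule), name)
        for name, m in monitors.items()
    ]
    return pd.concat(frames, ignore_index=True)


def summarize_minute_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-fly-day summaries from a normalized minute table."""
    missing = (
        (table["valid"].to_numpy() == 0) if "valid" in table.columns else None
    )
    rows = []
    for col in table.columns:
        if ":" not in col:
            continue
        for s in score_fly(table[col].to_numpy(), fly=col, missing=missing):
            rows.append(dataclasses.asdict(s))
    return pd.DataFrame(rows)


def sleep_profile(
    counts: np.ndarray,
    bin_width: int = 30,
    missing: np.ndarray | None = None,
) -> pd.DataFrame:
    """Binned fraction-asleep trace with per-bin SEM over flies.

    ``counts`` is (minutes x flies).  Each bin's value for one fly is
    its sleep minutes in the bin divided by ``bin_width``; the trace is
    the across-fly mean with SEM (0 when the group has a single fly).
    """
    if MINUTES_PER_DAY % bin_width != 0:
        raise SleepScoringError("bin_width must divide 1440")
    counts = np.asarray(counts)
    if counts.ndim == 1:
        counts = counts.reshape(-1, 1)
    n_minutes, n_flies = counts.shape
    n_bins = n_minutes // bin_width
    fractions = np.empty((n_bins, n_flies))
    for j in range(n_flies):
        st = sleep_state(counts[:, j], missing=missing)
        fractions[:, j] = (
            st[: n_bins * bin_width].reshape(n_bins, bin_width).mean(axis=1)
        )
    mean = fractions.mean(axis=1)
    if n_flies > 1:
        sem = fractions.std(axis=1, ddof=1) / np.sqrt(n_flies)
    else:
        sem = np.zeros(n_bins)
    return pd.DataFrame(
        {
            "bin_start_minute": np.arange(n_bins) * bin_width,
            "fraction_asleep": mean,
            "sem": sem,
        }
    )


def filter_dead_flies(
    counts: np.ndarray,
    min_dead_minutes: int = 720,
    fly_ids: list[str] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag flies inactive from some minute through the end of recording.

    A fly is excluded when its terminal zero-activity run lasts at least
    ``min_dead_minutes`` (default 12 h) or when it never moved at all.
    Returns an include mask plus a report of every fly's last active
    minute (-1 for never active); exclusions are reported, never silent.
    """
    counts = np.asarray(counts)
    if counts.ndim == 1:
        counts = counts.reshape(-1, 1)
    n_minutes, n_flies = counts.shape
    if fly_ids is None:
        fly_ids = [f"fly{j + 1}" for j in range(n_flies)]
    include = np.ones(n_flies, dtype=bool)
    last_active = np.full(n_flies, -1, dtype=int)
    for j in range(n_flies):
        active = np.flatnonzero(counts[:, j] > 0)
        if len(active) == 0:
            include[j] = False
            continue
        last_active[j] = int(active[-1])
        if n_minutes - 1 - last_active[j] >= min_dead_minutes:
            include[j] = False
    report = pd.DataFrame(
        {
            "fly": fly_ids,
            "last_active_minute": last_active,
            "include": include,
        }
    )
    return include, report
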