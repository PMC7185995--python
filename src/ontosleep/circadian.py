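"""FFT rhythmicity analysis of free-running (DD) locomotor activity.

The "FFT value" of a fly is defined here as band-limited relative
spectral power: the per-minute activity series is pre-binned (30-min
bins by default), mean-subtracted, discrete-Fourier transformed with no
zero padding, and each non-DC bin's power is expressed as a fraction of
the total non-DC power (interior one-sided bins doubled so the
fractions account for the full two-sided spectrum).  The FFT value is
the largest fraction at a period inside the circadian band (18-30 h by
default) and the peak period is that bin's period.  A fly is classified
rhythmic when the FFT value reaches a configurable threshold (default
0.04 — an operational choice, not a published constant).

This normalization makes the FFT value invariant to adding a constant
to the series and to positive rescaling; the frequency grid is fixed by
the window length (frequency resolution 1/window).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .dam_io import MINUTES_PER_DAY

DEFAULT_BIN_MINUTES = 30
DEFAULT_BAND_HOURS = (18.0, 30.0)
DEFAULT_RHYTHM_THRESHOLD = 0.04


@dataclasses.dataclass
class Periodogram:
    """One-sided relative power spectrum of an activity series."""

    periods: np.ndarray
    relative_power: np.ndarray
    peak_period: float
    fft_value: float
    band_hours: tuple[float, float]
    bin_minutes: int
    degenerate: bool = False


def select_days(counts: np.ndarray, first_day: int, last_day: int) -> np.ndarray:
    """Slice whole days (inclusive, 0-based) from a ZT-aligned series."""
    if first_day < 0 or last_day < first_day:
        raise ValueError("need 0 <= first_day <= last_day")
    lo = first_day * MINUTES_PER_DAY
    hi = (last_day + 1) * MINUTES_PER_DAY
    if hi > len(counts):
        raise ValueError(
            f"recording has {len(counts) // MINUTES_PER_DAY} days; "
            f"cannot select days {first_day}-{last_day}"
        )
    return np.asarray(counts)[lo:hi]


def fft_rhythm_analysis(
    counts: np.ndarray,
    bin_minutes: int = DEFAULT_BIN_MINUTES,
    band_hours: tuple[float, float] = DEFAULT_BAND_HOURS,
) -> Periodogram:
    """Periodogram and FFT value of a per-minute activity series.

    Requires at least two days of data so the circadian band is
    resolvable.  An all-zero (or constant) series has no non-DC power
    and is returned flagged degenerate with FFT value 0.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("counts must be a 1-D minute series")
    if len(x) < 2 * MINUTES_PER_DAY:
        raise ValueError("need at least 2 days of activity for FFT analysis")
    if bin_minutes < 1:
        raise ValueError("bin_minutes must be >= 1")
    n_bins = len(x) // bin_minutes
    binned = x[: n_bins * bin_minutes].reshape(n_bins, bin_minutes).mean(axis=1)
    y = binned - binned.mean()
    spec = np.fft.rfft(y)
    # One-sided power with interior bins doubled; DC excluded.
    power = np.abs(spec) ** 2
    weights = np.full(len(power), 2.0)
    weights[0] = 1.0
    if n_bins % 2 == 0:
        weights[-1] = 1.0
    power = power * weights
    nondc = power[1:]
    total = nondc.sum()
    window_hours = n_bins * bin_minutes / 60.0
    periods = window_hours / np.arange(1, len(power))
    if total <= 0.0:
        return Periodogram(
            periods=periods,
            relative_power=np.zeros_like(nondc),
            peak_period=float("nan"),
            fft_value=0.0,
            band_hours=band_hours,
            bin_minutes=bin_minutes,
            degenerate=True,
        )
    rel = nondc / total
    in_band = (periods >= band_hours[0]) & (periods <= band_hours[1])
    if not in_band.any():
        raise ValueError(
            f"no frequency bin falls in the {band_hours} h band; "
            "use a longer window or wider band"
        )
    band_idx = np.flatnonzero(in_band)
    k = band_idx[np.argmax(rel[band_idx])]
    return Periodogram(
        periods=periods,
        relative_power=rel,
        peak_period=float(periods[k]),
        fft_value=float(rel[k]),
        band_hours=band_hours,
        bin_minutes=bin_minutes,
    )


def classify_rhythmicity(
    p: Periodogram, threshold: float = DEFAULT_RHYTHM_THRESHOLD
) -> tuple[bool, dict]:
    """Rhythmic iff the FFT value reaches ``threshold``.

    Degenerate periodograms (no non-DC power) are classified arrhythmic
    and flagged in the report row.
    """
    rhythmic = bool(not p.degenerate and p.fft_value >= threshold)
    report = {
        "fft_value": p.fft_value,
        "peak_period_h": p.peak_period,
        "threshold": threshold,
        "rhythmic": rhythmic,
        "degenerate": p.degenerate,
    }
    return rhythmic, report
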