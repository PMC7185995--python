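"""Generators for synthetic fly activity, image stacks, and omics tables
with known ground truth.

The sleep-wake simulator is a semi-Markov alternating-renewal model:
a fly alternates between sleep and wake bouts whose durations are drawn
from age- and phase-specific geometric-tail distributions, so bout
length — the key architecture metric — is parameterized directly.
Sleep bouts are drawn as 4 + Geometric (support >= 5, hence always
detectable by the 5-minute rule) and wake bouts as Geometric (support
>= 1).  Under this model the expected fraction of a phase spent asleep
is mean_sleep / (mean_sleep + mean_wake), which lets day-phase sleep —
and therefore the expected ontogeny ratio — be set analytically.

Wild-type defaults are calibrated so young flies sleep about 1.75x as
much during the day as mature flies (the middle of the 1.5-2.0 band
typical of control genotypes), with night sleep high and age-invariant.
Waking activity is Poisson with an optional sinusoidal circadian
multiplier; zero-count wake minutes are re-drawn to 1 with a capped
probability so wake is rarely mistaken for sleep.

All generators take explicit seeds and are bit-reproducible; every
artifact is emitted alongside its ground truth.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .dam_io import (
    MINUTES_PER_DAY,
    N_CHANNELS,
    ActivityMatrix,
    LightSchedule,
    make_timestamps,
    validate_design,
    write_dam_file,
    write_design,
)
from .imaging_quant import ImageStack, RoiMask
from .sleep_metrics import DAY_MINUTES

AGES = ("young", "mature")
PHASES = ("day", "night")


class ModelValidationError(ValueError):
    """A generator model violates one of its invariants."""


class PlacementError(RuntimeError):
    """The ROI cannot hold the requested number of disjoint blobs."""


@dataclasses.dataclass(frozen=True)
class BoutParams:
    """Mean sleep- and wake-bout durations (minutes) for one (age, phase)."""

    sleep_mean: float
    wake_mean: float

    @property
    def sleep_fraction(self) -> float:
        """Stationary fraction of time asleep under alternating renewal."""
        return self.sleep_mean / (self.sleep_mean + self.wake_mean)


def _bout_params_for_fraction(sleep_mean: float, fraction: float) -> BoutParams:
    """Bout parameters achieving a target stationary sleep fraction."""
    if not 0.0 < fraction < 1.0:
        raise ModelValidationError("sleep fraction must be in (0, 1)")
    return BoutParams(sleep_mean, sleep_mean * (1.0 - fraction) / fraction)


@dataclasses.dataclass
class GenotypeModel:
    """Generative sleep-wake parameters for one genotype.

    ``bout_params`` maps (age, phase) to bout-duration means.  The
    circadian term multiplies the waking Poisson rate by
    ``1 + amplitude * cos(2*pi*t / period)`` (peaking at ZT0) when the
    genotype is rhythmic; arrhythmic genotypes get a flat rate.
    """

    bout_params: dict[tuple[str, str], BoutParams]
    activity_rate: float = 2.0
    circadian_amplitude: float = 0.3
    circadian_period_h: float = 24.0
    wake_fill_p: float = 0.85
    rhythmic: bool = True

    def validate(self) -> None:
        problems = []
        for age in AGES:
            for phase in PHASES:
                p = self.bout_params.get((age, phase))
                if p is None:
                    problems.append(f"missing bout params for ({age}, {phase})")
                    continue
                if p.sleep_mean < 5:
                    problems.append(
                        f"({age}, {phase}): sleep-bout mean {p.sleep_mean} < 5 "
                        "(bouts must be detectable)"
                    )
                if p.wake_mean < 1:
                    problems.append(
                        f"({age}, {phase}): wake-bout mean {p.wake_mean} < 1"
                    )
        if self.activity_rate <= 0:
            problems.append("activity_rate must be > 0")
        if not 0.0 <= self.circadian_amplitude <= 1.0:
            problems.append("circadian_amplitude must be in [0, 1]")
        if self.circadian_period_h <= 0:
            problems.append("circadian_period_h must be > 0")
        if not 0.0 <= self.wake_fill_p <= 1.0:
            problems.append("wake_fill_p must be in [0, 1]")
        if problems:
            raise ModelValidationError("; ".join(problems))

    def expected_phase_sleep(self, age: str, phase: str) -> float:
        """Expected sleep minutes in one 720-min phase block."""
        return DAY_MINUTES * self.bout_params[(age, phase)].sleep_fraction

    @property
    def expected_ontogeny_ratio(self) -> float:
        return (
            self.expected_phase_sleep("young", "day")
            / self.expected_phase_sleep("mature", "day")
        )

    @classmethod
    def wild_type(
        cls,
        target_ontogeny_ratio: float = 1.75,
        mature_day_fraction: float = 0.35,
        night_fraction: float = 0.8,
        young_day_sleep_mean: float = 40.0,
        mature_day_sleep_mean: float = 15.0,
        night_sleep_mean: float = 45.0,
        **kwargs,
    ) -> "GenotypeModel":
        """Control genotype with an analytically calibrated ontogeny ratio.

        The young daytime sleep fraction is set to ``target * mature
        fraction``, with the extra young sleep carried by longer bouts
        (young consolidation), matching how juvenile daytime sleep is
        organized in control flies.
        """
        young_day_fraction = target_ontogeny_ratio * mature_day_fraction
        if not young_day_fraction < 0.97:
            raise ModelValidationError(
                "target ratio too high for the chosen mature day fraction"
            )
        model = cls(
            bout_params={
                ("young", "day"): _bout_params_for_fraction(
                    young_day_sleep_mean, young_day_fraction
                ),
                ("mature", "day"): _bout_params_for_fraction(
                    mature_day_sleep_mean, mature_day_fraction
                ),
                ("young", "night"): _bout_params_for_fraction(
                    night_sleep_mean, night_fraction
                ),
                ("mature", "night"): _bout_params_for_fraction(
                    night_sleep_mean, night_fraction
                ),
            },
            **kwargs,
        )
        model.validate()
        return model

    @classmethod
    def flat(cls, day_fraction: float = 0.35, **kwargs) -> "GenotypeModel":
        """No ontogenetic change: young and mature share all parameters."""
        return cls.wild_type(
            target_ontogeny_ratio=1.0,
            mature_day_fraction=day_fraction,
            young_day_sleep_mean=15.0,
            **kwargs,
        )

    @classmethod
    def arrhythmic(cls, fraction: float = 0.5, **kwargs) -> "GenotypeModel":
        """No day/night structure and no circadian activity modulation."""
        params = _bout_params_for_fraction(20.0, fraction)
        model = cls(
            bout_params={(a, p): params for a in AGES for p in PHASES},
            circadian_amplitude=0.0,
            rhythmic=False,
            **kwargs,
        )
        model.validate()
        return model

    def fragmented(self, factor: float) -> "GenotypeModel":
        """Shorter bouts at unchanged sleep fractions (architecture change).

        Both bout means are scaled by ``factor`` (< 1 fragments sleep);
        sleep-bout means are floored at 5 so bouts stay detectable, with
        the wake mean rescaled to preserve the phase sleep fraction.
        """
        if factor <= 0:
            raise ModelValidationError("fragmentation factor must be > 0")
        new = {}
        for key, p in self.bout_params.items():
            sleep = max(5.0, p.sleep_mean * factor)
            new[key] = _bout_params_for_fraction(sleep, p.sleep_fraction)
        model = dataclasses.replace(self, bout_params=new)
        model.validate()
        return model


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw_sleep_bout(rng: np.random.Generator, mean: float) -> int:
    if mean <= 5.0:
        return 5
    return 4 + int(rng.geometric(1.0 / (mean - 4.0)))


def _draw_wake_bout(rng: np.random.Generator, mean: float) -> int:
    if mean <= 1.0:
        return 1
    return int(rng.geometric(1.0 / mean))


def _draw_residual_sleep(rng: np.random.Generator, mean: float) -> int:
    """Equilibrium residual life of the 4 + Geometric sleep-bout law.

    For X = 4 + Geometric(p), P(residual = k) = P(X >= k) / E[X]; the
    survival is flat over the first five minutes and geometric beyond,
    so the residual is uniform on {1..5} with probability 5/mean and
    5 + Geometric(p) otherwise.
    """
    if mean <= 5.0:
        return int(rng.integers(1, 6))
    if rng.random() < 5.0 / mean:
        return int(rng.integers(1, 6))
    return 5 + int(rng.geometric(1.0 / (mean - 4.0)))


def _draw_residual_wake(rng: np.random.Generator, mean: float) -> int:
    # Geometric bouts are memoryless: the residual is the full law.
    return _draw_wake_bout(rng, mean)


def simulate_fly_activity(
    model: GenotypeModel,
    age: str,
    n_minutes: int,
    seed,
    start_zt_minute: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute counts plus the latent sleep-state sequence.

    The fly alternates sleep/wake bouts within each 720-min phase block;
    lights transitions (ZT0, ZT12) reset behaviour, truncating the bout
    in progress.  Each block starts in its stationary state: asleep with
    the phase's equilibrium probability and with an equilibrium
    residual-life first bout, so the expected sleep fraction of every
    block equals mean_sleep / (mean_sleep + mean_wake) exactly.  Counts
    are 0 while asleep and Poisson (circadian-modulated) while awake,
    with zero wake minutes re-drawn to 1 with probability
    ``wake_fill_p``.
    """
    model.validate()
    if age not in AGES:
        raise ValueError(f"age must be one of {AGES}")
    if n_minutes < MINUTES_PER_DAY:
        raise ValueError("n_minutes must be >= 1440 (one full day)")
    rng = _as_rng(seed)
    latent = np.zeros(n_minutes, dtype=bool)
    t = 0
    while t < n_minutes:
        zt = (start_zt_minute + t) % MINUTES_PER_DAY
        phase = "day" if zt < DAY_MINUTES else "night"
        p = model.bout_params[(age, phase)]
        block_end = t + (DAY_MINUTES - zt % DAY_MINUTES)
        asleep = bool(rng.random() < p.sleep_fraction)
        first = True
        while t < min(block_end, n_minutes):
            if asleep:
                dur = (
                    _draw_residual_sleep(rng, p.sleep_mean)
                    if first
                    else _draw_sleep_bout(rng, p.sleep_mean)
                )
                latent[t : min(t + dur, block_end, n_minutes)] = True
            else:
                dur = (
                    _draw_residual_wake(rng, p.wake_mean)
                    if first
                    else _draw_wake_bout(rng, p.wake_mean)
                )
            t += dur
            asleep = not asleep
            first = False
        t = block_end  # truncate the bout in progress at the transition
    abs_minute = start_zt_minute + np.arange(n_minutes)
    if model.rhythmic and model.circadian_amplitude > 0:
        mult = 1.0 + model.circadian_amplitude * np.cos(
            2.0 * np.pi * abs_minute / (model.circadian_period_h * 60.0)
        )
    else:
        mult = np.ones(n_minutes)
    counts = np.zeros(n_minutes, dtype=np.int64)
    wake = ~latent
    counts[wake] = rng.poisson(model.activity_rate * mult[wake])
    zero_wake = np.flatnonzero(wake & (counts == 0))
    fill = rng.random(len(zero_wake)) < model.wake_fill_p
    counts[zero_wake[fill]] = 1
    return counts, latent


@dataclasses.dataclass
class ScreenSimulation:
    """Simulated multi-monitor screen with design table and ground truth."""

    monitors: dict[str, ActivityMatrix]
    design: pd.DataFrame
    schedule: LightSchedule
    #: genotype -> {"expected_ratio": float}
    truth: dict[str, dict]
    #: fly id -> latent daytime-sleep minutes for each full aligned day
    latent_day_sleep: dict[str, np.ndarray]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, m in self.monitors.items():
            write_dam_file(m, out / f"{name}.txt")
        write_design(self.design, out / "design.tsv")
        (out / "truth.json").write_text(
            json.dumps(self.truth, indent=2, sort_keys=True)
        )


def simulate_screen_experiment(
    models: dict[str, GenotypeModel],
    n_flies_per_group: int = 16,
    seed=0,
    n_days: int = 2,
    start_zt_minute: int = 1080,
    lights_on: dt.time = dt.time(6, 0),
    start_date: dt.date = dt.date(2026, 1, 5),
) -> ScreenSimulation:
    """Simulate a sleep-ontogeny screen as DAM-format monitor data.

    Young and mature flies of every genotype are packed 32 to a
    monitor.  The recording starts at ``start_zt_minute`` (default
    ZT18, emulating loading the evening before) and continues for
    ``n_days`` full days past the next ZT0, so Zeitgeber alignment
    yields exactly ``n_days`` scored days per fly.
    """
    if not models:
        raise ValueError("at least one genotype model is required")
    if n_flies_per_group < 1:
        raise ValueError("n_flies_per_group must be >= 1")
    rng = _as_rng(seed)
    lead = (-start_zt_minute) % MINUTES_PER_DAY
    if lead == 0:
        lead = MINUTES_PER_DAY  # start exactly at ZT0 still drops a day
    n_minutes = lead + n_days * MINUTES_PER_DAY
    start_dt = dt.datetime.combine(start_date, lights_on) + dt.timedelta(
        minutes=start_zt_minute
    )
    timestamps = make_timestamps(start_dt, n_minutes)

    flies = [
        (genotype, age)
        for genotype in models
        for age in AGES
        for _ in range(n_flies_per_group)
    ]
    monitors: dict[str, ActivityMatrix] = {}
    design_rows = []
    latent_day_sleep: dict[str, np.ndarray] = {}
    day_zt = np.arange(n_days * MINUTES_PER_DAY) % MINUTES_PER_DAY < DAY_MINUTES

    for start in range(0, len(flies), N_CHANNELS):
        block = flies[start : start + N_CHANNELS]
        name = f"Monitor{start // N_CHANNELS + 1}"
        counts = np.zeros((n_minutes, N_CHANNELS), dtype=np.int64)
        for ch, (genotype, age) in enumerate(block):
            c, latent = simulate_fly_activity(
                models[genotype], age, n_minutes, rng,
                start_zt_minute=start_zt_minute,
            )
            counts[:, ch] = c
            aligned_latent = latent[lead:]
            per_day = (
                (aligned_latent & day_zt)
                .reshape(n_days, MINUTES_PER_DAY)
                .sum(axis=1)
            )
            fid = f"{name}:{ch + 1}"
            latent_day_sleep[fid] = per_day
            design_rows.append(
                {
                    "monitor": name,
                    "channel": ch + 1,
                    "genotype": genotype,
                    "age_class": age,
                    "include": True,
                }
            )
        # Unused trailing channels stay all-zero and are left out of the
        # design table, mirroring partially loaded monitors.
        monitors[name] = ActivityMatrix(
            timestamps=timestamps,
            counts=counts,
            status=np.ones(n_minutes, dtype=np.int64),
        )
    design = validate_design(pd.DataFrame(design_rows))
    schedule = LightSchedule(lights_on=lights_on, photoperiod_hours=12.0)
    truth = {
        g: {"expected_ratio": m.expected_ontogeny_ratio}
        for g, m in models.items()
    }
    return ScreenSimulation(
        monitors=monitors,
        design=design,
        schedule=schedule,
        truth=truth,
        latent_day_sleep=latent_day_sleep,
    )


# ---------------------------------------------------------------------------
# Image stacks


def _grow_blob(
    rng: np.random.Generator,
    start: tuple[int, int, int],
    size: int,
    allowed: np.ndarray,
) -> list[tuple[int, int, int]] | None:
    """Grow a 26-connected voxel set of exactly ``size`` inside ``allowed``."""
    shape = allowed.shape
    blob = {start}
    frontier = [start]
    while len(blob) < size and frontier:
        i = rng.integers(len(frontier))
        z, y, x = frontier[i]
        neighbors = [
            (z + dz, y + dy, x + dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if not (dz == dy == dx == 0)
        ]
        candidates = [
            v
            for v in neighbors
            if 0 <= v[0] < shape[0]
            and 0 <= v[1] < shape[1]
            and 0 <= v[2] < shape[2]
            and allowed[v]
            and v not in blob
        ]
        if not candidates:
            frontier.pop(i)
            continue
        v = candidates[rng.integers(len(candidates))]
        blob.add(v)
        frontier.append(v)
    return sorted(blob) if len(blob) == size else None


def simulate_image_stack(
    k_puncta: int,
    blob_size_range: tuple[int, int] = (2, 80),
    intensity: float = 60.0,
    noise_sd: float = 5.0,
    background_mean: float = 10.0,
    noise_clip: tuple[float, float] = (1.0, 45.0),
    shape: tuple[int, int, int] = (12, 48, 48),
    roi_margin: int = 3,
    seed=None,
    max_tries: int = 200,
) -> tuple[ImageStack, RoiMask, list[dict]]:
    """Synthetic confocal stack with ``k_puncta`` disjoint bright blobs.

    Blobs are 26-connected voxel sets of recorded sizes placed inside a
    box-shaped ROI with at least one voxel of separation, over clipped
    Gaussian background noise.  The noise clip keeps every background
    voxel strictly between 1 and the blob intensity, so (a) the planted
    blobs are exactly the supra-threshold components for any threshold
    in that gap, and (b) the ROI volume at the >= 1 intensity rule is
    the full ROI.  Ground truth lists every blob's voxels and size.
    """
    if k_puncta < 0:
        raise ValueError("k_puncta must be >= 0")
    lo, hi = blob_size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid blob size range")
    if not 0 < noise_clip[0] <= noise_clip[1] < intensity:
        raise ValueError("noise clip must satisfy 0 < lo <= hi < intensity")
    rng = _as_rng(seed)
    roi = np.zeros(shape, dtype=bool)
    roi[:, roi_margin:-roi_margin or None, roi_margin:-roi_margin or None] = True
    vox = np.clip(
        rng.normal(background_mean, noise_sd, size=shape),
        noise_clip[0],
        noise_clip[1],
    )
    occupied = np.zeros(shape, dtype=bool)
    forbidden = np.zeros(shape, dtype=bool)
    truth: list[dict] = []
    for _ in range(k_puncta):
        size = int(rng.integers(lo, hi + 1))
        allowed = roi & ~forbidden
        blob = None
        for _attempt in range(max_tries):
            starts = np.argwhere(allowed)
            if len(starts) == 0:
                break
            start = tuple(starts[rng.integers(len(starts))])
            blob = _grow_blob(rng, start, size, allowed)
            if blob is not None:
                break
        if blob is None:
            raise PlacementError(
                f"could not place {k_puncta} disjoint blobs of sizes "
                f"{blob_size_range} in the ROI"
            )
        idx = tuple(np.array(blob).T)
        vox[idx] = intensity
        occupied[idx] = True
        forbidden = ndimage.binary_dilation(
            occupied, structure=np.ones((3, 3, 3), dtype=bool)
        )
        truth.append({"size": size, "voxels": blob})
    stack = ImageStack(voxels=vox)
    return stack, RoiMask(mask=roi, label="dFSB"), truth


# ---------------------------------------------------------------------------
# Omics tables


def simulate_omics_tables(
    n_genes: int = 2000,
    n_up: int = 54,
    n_down: int = 35,
    n_top_peaks: int = 200,
    n_overlap: int = 5,
    seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Toy DE and ChIP-peak tables with planted memberships.

    Defaults plant 54 upregulated and 35 downregulated genes, a
    200-gene top peak set, and a five-gene overlap between them — the
    set sizes characteristic of a mid-pupal knockdown transcriptome
    crossed with a transcription-factor ChIP experiment.  Standard
    selection (padj < 0.05, |log2FC| > 1) and top-N ranking recover the
    planted sets exactly.
    """
    if n_overlap > min(n_up + n_down, n_top_peaks):
        raise ValueError("n_overlap exceeds the planted set sizes")
    if n_up + n_down + n_top_peaks - n_overlap > n_genes:
        raise ValueError("n_genes too small for the requested memberships")
    rng = _as_rng(seed)
    genes = np.array([f"g{i:05d}" for i in range(n_genes)])
    perm = rng.permutation(n_genes)
    up = genes[perm[:n_up]]
    down = genes[perm[n_up : n_up + n_down]]
    null = genes[perm[n_up + n_down :]]

    padj = rng.uniform(0.05, 1.0, size=n_genes)
    lfc = rng.normal(0.0, 0.4, size=n_genes)
    by_gene = {g: i for i, g in enumerate(genes)}
    for g in up:
        padj[by_gene[g]] = rng.uniform(1e-8, 0.049)
        lfc[by_gene[g]] = rng.uniform(1.01, 3.0)
    for g in down:
        padj[by_gene[g]] = rng.uniform(1e-8, 0.049)
        lfc[by_gene[g]] = -rng.uniform(1.01, 3.0)
    # A near-miss at the exact adjusted-p boundary: excluded under the
    # strict inequality.
    if len(null):
        boundary = null[0]
        padj[by_gene[boundary]] = 0.05
        lfc[by_gene[boundary]] = 2.5
    de = pd.DataFrame({"gene": genes, "log2fc": lfc, "padj": padj})

    de_genes = np.concatenate([up, down])
    overlap = rng.choice(de_genes, size=n_overlap, replace=False)
    n_other_top = n_top_peaks - n_overlap
    other_top = null[1 : 1 + n_other_top]
    top_genes = np.concatenate([overlap, other_top])
    peak_rows = []
    top_p = np.sort(rng.uniform(1e-10, 1e-4, size=n_top_peaks))
    order = rng.permutation(n_top_peaks)
    for g, p in zip(top_genes[order], top_p):
        peak_rows.append(
            {"gene": g, "pvalue": p, "signal": float(rng.uniform(5, 50))}
        )
    # Secondary (weaker) peaks for some top genes: best-peak ranking
    # must ignore them.
    for g in top_genes[: min(10, len(top_genes))]:
        peak_rows.append(
            {
                "gene": g,
                "pvalue": float(rng.uniform(1e-3, 0.5)),
                "signal": float(rng.uniform(1, 5)),
            }
        )
    # Background peaks on genes outside the top set, all with worse
    # p-values than every top peak.
    n_background = min(200, len(null) - 1 - n_other_top)
    for g in null[1 + n_other_top : 1 + n_other_top + n_background]:
        peak_rows.append(
            {
                "gene": g,
                "pvalue": float(rng.uniform(1e-3, 0.5)),
                "signal": float(rng.uniform(1, 20)),
            }
        )
    peaks = pd.DataFrame(peak_rows).sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    de = de.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    truth = {
        "up": set(up),
        "down": set(down),
        "top_peak_genes": set(top_genes),
        "overlap": set(overlap),
        "boundary_gene": boundary if len(null) else None,
    }
    return de, peaks, truth
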