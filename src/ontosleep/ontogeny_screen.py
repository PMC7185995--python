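"""Ontogeny-ratio screening, hit calling, and the screen's statistics.

The ontogeny ratio (OR) of a genotype is

    OR = mean daytime sleep of day-1 (young) flies
         / mean daytime sleep of day-4-5 (mature) flies,

a ratio of group means: young and mature flies are different
individuals, so per-fly ratios are impossible.  Wild-type genotypes sit
around 1.5-2.0 (young flies sleep roughly twice as much by day); an OR
near 1 means the developmental decline in sleep is missing.  Screen
hits are genotypes with OR <= 1.2 (inclusive).

Statistical comparisons follow the screen's conventions: families of
two-sample t tests corrected by the Holm-Sidak step-down procedure,
Welch's t for single two-group contrasts, and one-way ANOVA with Tukey's
HSD for three or more groups.  All tests are two-tailed with alpha 0.05
by default.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_CUTOFF = 1.2
DEFAULT_MIN_N = 8
DEFAULT_ALPHA = 0.05


@dataclasses.dataclass
class OntogenyResult:
    """Per-genotype young/mature daytime-sleep distributions and ratio."""

    genotype: str
    young_day_sleep: np.ndarray
    mature_day_sleep: np.ndarray
    n_young: int = 0
    n_mature: int = 0
    young_mean: float = float("nan")
    mature_mean: float = float("nan")
    ontogeny_ratio: float = float("nan")
    ratio_defined: bool = False
    hit: bool | None = None


@dataclasses.dataclass
class StatResult:
    """One comparison: statistic, raw and adjusted p, significance call."""

    comparison: str
    statistic: float
    p_raw: float
    p_adj: float = float("nan")
    alpha: float = DEFAULT_ALPHA
    significant: bool = False
    df: float = float("nan")
    note: str = ""


@dataclasses.dataclass
class ModifierResult:
    """Modifier-screen contrast of a modified genotype against its base."""

    base_genotype: str
    modified_genotype: str
    ratio_delta: float
    rescue: bool
    young_contrast: StatResult | None
    mature_contrast: StatResult | None
    modified_ontogeny_contrast: StatResult | None
    note: str = ""


def compute_ontogeny_ratio(
    young: np.ndarray, mature: np.ndarray, genotype: str = ""
) -> OntogenyResult:
    """Ratio of group means of per-fly daytime sleep minutes.

    A mature mean of zero leaves the ratio undefined (``ratio_defined``
    False, ratio NaN); such genotypes are reported but excluded from hit
    ranking — a genotype that never sleeps is an assay failure, not an
    ontogeny hit.
    """
    young = np.asarray(young, dtype=float)
    mature = np.asarray(mature, dtype=float)
    if young.size == 0 or mature.size == 0:
        raise ValueError("both age groups must be non-empty")
    ym, mm = float(young.mean()), float(mature.mean())
    defined = mm > 0
    return OntogenyResult(
        genotype=genotype,
        young_day_sleep=young,
        mature_day_sleep=mature,
        n_young=young.size,
        n_mature=mature.size,
        young_mean=ym,
        mature_mean=mm,
        ontogeny_ratio=ym / mm if defined else float("nan"),
        ratio_defined=defined,
    )


def ratios_from_day_sleep(
    day_sleep: pd.DataFrame, day_policy: str = "first"
) -> list[OntogenyResult]:
    """Per-genotype ratios from a (genotype, age_class, fly, day, day_sleep) table.

    ``day_policy`` reduces multiple recorded days per fly to one value:
    ``"first"`` uses the first full recorded day, ``"mean"`` averages
    all recorded days.
    """
    if day_policy not in ("first", "mean"):
        raise ValueError("day_policy must be 'first' or 'mean'")
    df = day_sleep.sort_values(["genotype", "age_class", "fly", "day"])
    if day_policy == "first":
        per_fly = df.groupby(
            ["genotype", "age_class", "fly"], sort=True
        )["day_sleep"].first()
    else:
        per_fly = df.groupby(
            ["genotype", "age_class", "fly"], sort=True
        )["day_sleep"].mean()
    results = []
    for genotype, sub in per_fly.groupby(level="genotype", sort=True):
        ages = sub.groupby(level="age_class").groups
        young = sub.xs("young", level="age_class").to_numpy() if "young" in ages else np.array([])
        mature = sub.xs("mature", level="age_class").to_numpy() if "mature" in ages else np.array([])
        if young.size == 0 or mature.size == 0:
            continue
        results.append(compute_ontogeny_ratio(young, mature, genotype=str(genotype)))
    return results


def call_screen_hits(
    results: list[OntogenyResult],
    cutoff: float = DEFAULT_CUTOFF,
    min_n: int = DEFAULT_MIN_N,
) -> pd.DataFrame:
    """Flag hits (ratio <= cutoff, boundary inclusive) and rank genotypes.

    Genotypes with fewer than ``min_n`` flies in either age group, or an
    undefined ratio, are reported with ``eligible`` False and never
    called as hits.  Output is sorted ascending by ratio (undefined
    ratios last).
    """
    rows = []
    for r in results:
        eligible = r.ratio_defined and r.n_young >= min_n and r.n_mature >= min_n
        hit = bool(eligible and r.ontogeny_ratio <= cutoff)
        r.hit = hit
        rows.append(
            {
                "genotype": r.genotype,
                "n_young": r.n_young,
                "n_mature": r.n_mature,
                "young_mean": r.young_mean,
                "mature_mean": r.mature_mean,
                "ontogeny_ratio": r.ontogeny_ratio,
                "ratio_defined": r.ratio_defined,
                "eligible": eligible,
                "hit": hit,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            "ontogeny_ratio", na_position="last", kind="mergesort"
        ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Statistics


def holm_sidak_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, in the input order.

    For sorted raw p-values p_(1) <= ... <= p_(m), the adjusted value is
    p~_(i) = max_{j<=i} [1 - (1 - p_(j))^(m - j + 1)], capped at 1.
    Works along the last axis for vectorized use.
    """
    p = np.asarray(p_raw, dtype=float)
    m = p.shape[-1]
    order = np.argsort(p, axis=-1, kind="stable")
    p_sorted = np.take_along_axis(p, order, axis=-1)
    exponents = m - np.arange(m)
    stepped = 1.0 - (1.0 - p_sorted) ** exponents
    adj_sorted = np.minimum(np.maximum.accumulate(stepped, axis=-1), 1.0)
    adj = np.empty_like(adj_sorted)
    np.put_along_axis(adj, order, adj_sorted, axis=-1)
    return adj


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool
) -> tuple[float, float, float, str]:
    """(t, p, df, note) with explicit handling of zero-variance groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0, float(a.size + b.size - 2), "degenerate: zero variance, equal means (p=1 by convention)"
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return sign * float("inf"), 0.0, float(a.size + b.size - 2), "degenerate: zero variance, unequal means (p->0)"
    if equal_var:
        t, p = stats.ttest_ind(a, b, equal_var=True)
        df = float(a.size + b.size - 2)
    else:
        # Welch statistic with Welch-Satterthwaite degrees of freedom.
        sa, sb = va / a.size, vb / b.size
        t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
        p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), float(df), ""


def holm_sidak_ttests(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    labels: list[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = True,
) -> list[StatResult]:
    """A family of two-sample two-tailed t tests, Holm-Sidak corrected.

    This is the screen's standard family-wise comparison ("multiple t
    tests with Holm-Sidak correction"); ``equal_var=False`` switches the
    underlying tests to Welch's form.
    """
    if labels is None:
        labels = [f"pair{i + 1}" for i in range(len(pairs))]
    raws, stats_, dfs, notes = [], [], [], []
    for a, b in pairs:
        t, p, df, note = _two_sample_t(a, b, equal_var=equal_var)
        raws.append(p)
        stats_.append(t)
        dfs.append(df)
        notes.append(note)
    adj = holm_sidak_adjust(np.array(raws)) if pairs else np.array([])
    return [
        StatResult(
            comparison=lab,
            statistic=t,
            p_raw=p,
            p_adj=float(pa),
            alpha=alpha,
            significant=bool(pa < alpha),
            df=df,
            note=note,
        )
        for lab, t, p, pa, df, note in zip(labels, stats_, raws, adj, dfs, notes)
    ]


def welch_ttest(
    a: np.ndarray,
    b: np.ndarray,
    comparison: str = "a vs b",
    alpha: float = DEFAULT_ALPHA,
) -> StatResult:
    """Unpaired two-tailed t test with Welch's correction."""
    t, p, df, note = _two_sample_t(a, b, equal_var=False)
    return StatResult(
        comparison=comparison,
        statistic=t,
        p_raw=p,
        p_adj=p,
        alpha=alpha,
        significant=bool(p < alpha),
        df=df,
        note=note,
    )


def anova_tukey(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[StatResult, list[StatResult]]:
    """One-way ANOVA followed by Tukey's HSD over all group pairs.

    Tukey adjusted p-values come from the studentized-range
    distribution.  Requires >= 3 groups (use a t test for two).
    """
    if len(groups) < 3:
        raise ValueError("anova_tukey requires >= 3 groups; use a t test")
    groups = [np.asarray(g, dtype=float) for g in groups]
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    f, p = stats.f_oneway(*groups)
    overall = StatResult(
        comparison="ANOVA",
        statistic=float(f),
        p_raw=float(p),
        p_adj=float(p),
        alpha=alpha,
        significant=bool(p < alpha),
        df=float(len(groups) - 1),
    )
    hsd = stats.tukey_hsd(*groups)
    pairwise = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            pp = float(hsd.pvalue[i, j])
            pairwise.append(
                StatResult(
                    comparison=f"{labels[i]} vs {labels[j]}",
                    statistic=float(hsd.statistic[i, j]),
                    p_raw=pp,
                    p_adj=pp,
                    alpha=alpha,
                    significant=bool(pp < alpha),
                )
            )
    return overall, pairwise


def modifier_contrast(
    base: OntogenyResult,
    modified: OntogenyResult,
    alpha: float = DEFAULT_ALPHA,
    min_ratio_gain: float = 0.0,
) -> ModifierResult:
    """Compare a co-knockdown genotype against its base knockdown.

    A "rescue" is flagged when the modified genotype's ratio exceeds the
    base ratio by more than ``min_ratio_gain`` *and* its young-vs-mature
    daytime-sleep contrast regains significance (Welch, two-tailed).
    Undefined ratios propagate as flagged non-rescues.
    """
    if not (base.ratio_defined and modified.ratio_defined):
        return ModifierResult(
            base_genotype=base.genotype,
            modified_genotype=modified.genotype,
            ratio_delta=float("nan"),
            rescue=False,
            young_contrast=None,
            mature_contrast=None,
            modified_ontogeny_contrast=None,
            note="undefined ratio in base or modified genotype",
        )
    delta = modified.ontogeny_ratio - base.ontogeny_ratio
    young_c = welch_ttest(
        modified.young_day_sleep, base.young_day_sleep,
        comparison="young: modified vs base", alpha=alpha,
    )
    mature_c = welch_ttest(
        modified.mature_day_sleep, base.mature_day_sleep,
        comparison="mature: modified vs base", alpha=alpha,
    )
    onto_c = welch_ttest(
        modified.young_day_sleep, modified.mature_day_sleep,
        comparison="modified: young vs mature", alpha=alpha,
    )
    rescue = bool(delta > min_ratio_gain and onto_c.significant)
    return ModifierResult(
        base_genotype=base.genotype,
        modified_genotype=modified.genotype,
        ratio_delta=float(delta),
        rescue=rescue,
        young_contrast=young_c,
        mature_contrast=mature_c,
        modified_ontogeny_contrast=onto_c,
    )
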