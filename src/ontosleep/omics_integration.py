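"""Gene-set logic downstream of RNA-Seq and ChIP-Seq.

Differentially expressed genes are selected with strict inequalities
(adjusted p < threshold and |log2 fold change| > threshold); two named
presets are shipped because the analysis was reported with both a
formal definition (|log2FC| > 1.0) and a looser summary (linear fold
change > 1.2).  ChIP peak genes are ranked by best-peak p-value with a
fully deterministic tie-break, and sets are intersected for a two-set
Venn.  Alignment, counting, differential testing, and peak calling are
upstream tools' jobs and deliberately out of scope — only their table
outputs are consumed here.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import pandas as pd

DE_COLUMNS = ("gene", "log2fc", "padj")
PEAK_COLUMNS = ("gene", "pvalue", "signal")

#: Named DE-threshold presets.  "methods" (|log2FC| > 1.0) is the
#: default because it is the formal analysis definition; "results"
#: reflects the linear fold-change > 1.2 phrasing.
DE_PRESETS: dict[str, dict[str, float]] = {
    "methods": {"padj_max": 0.05, "lfc_min": 1.0},
    "results": {"padj_max": 0.05, "lfc_min": math.log2(1.2)},
}

DEFAULT_TOP_N = 200


class SchemaError(ValueError):
    """A table is missing required columns."""


@dataclasses.dataclass
class DeSelection:
    up: set[str]
    down: set[str]
    padj_max: float
    lfc_min: float


@dataclasses.dataclass
class VennCounts:
    overlap: set[str]
    n_a_only: int
    n_b_only: int
    n_overlap: int


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"table missing required columns: {missing}")


def select_de_genes(
    table: pd.DataFrame, padj_max: float = 0.05, lfc_min: float = 1.0
) -> DeSelection:
    """Up- and down-regulated gene sets under strict thresholds.

    up   = {padj < padj_max and log2fc > lfc_min}
    down = {padj < padj_max and log2fc < -lfc_min}

    Both inequalities are strict, so a gene at exactly the adjusted-p
    threshold is excluded.
    """
    if padj_max <= 0 or lfc_min <= 0:
        raise ValueError("thresholds must be positive")
    _require_columns(table, DE_COLUMNS)
    sig = table["padj"] < padj_max
    up = set(table.loc[sig & (table["log2fc"] > lfc_min), "gene"])
    down = set(table.loc[sig & (table["log2fc"] < -lfc_min), "gene"])
    return DeSelection(up=up, down=down, padj_max=padj_max, lfc_min=lfc_min)


def top_chip_genes(table: pd.DataFrame, n: int = DEFAULT_TOP_N) -> list[str]:
    """The first ``n`` unique genes ranked by best ChIP peak.

    Each gene is scored by its strongest peak (minimum p-value; ties by
    maximum signal).  Genes are then ranked by p-value ascending, ties
    broken by signal descending, then gene id lexicographically, making
    the ordering total and deterministic under row shuffles.  Smaller
    p-values rank higher — convert -log10 scores (narrowPeak) before
    calling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    _require_columns(table, PEAK_COLUMNS)
    best = (
        table.sort_values(
            ["pvalue", "signal", "gene"],
            ascending=[True, False, True],
            kind="mergesort",
        )
        .drop_duplicates(subset="gene", keep="first")
    )
    ranked = best.sort_values(
        ["pvalue", "signal", "gene"],
        ascending=[True, False, True],
        kind="mergesort",
    )["gene"].tolist()
    if n > len(ranked):
        warnings.warn(
            f"requested top {n} genes but only {len(ranked)} unique genes "
            "are present; returning all",
            stacklevel=2,
        )
    return ranked[:n]


def intersect_gene_sets(a: set[str], b: set[str]) -> VennCounts:
    """Two-set Venn: overlap plus exclusive counts."""
    a, b = set(a), set(b)
    overlap = a & b
    return VennCounts(
        overlap=overlap,
        n_a_only=len(a - b),
        n_b_only=len(b - a),
        n_overlap=len(overlap),
    )


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, DE_COLUMNS)
    return df


def read_peak_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, PEAK_COLUMNS)
    return df
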