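"""Pairwise alteration co-occurrence / mutual-exclusivity statistics.

Given binary per-sample alteration calls (mutation / CNA / expression /
structural variant collapsed to 0/1 per gene), each gene pair is summarised
by its 2x2 contingency table, the odds ratio, a Fisher exact p-value
(one-sided toward the observed direction, as in cBioPortal's
mutual-exclusivity module), and a BH-adjusted q across the pair family.

The log2 odds ratio is additionally rendered in the cBioPortal display
convention: values above 3 print as ">3" and below -3 as "<-3".
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .enrichment import bh_adjust

LOG2_DISPLAY_CAP = 3.0

CO_OCCURRENCE = "Co-occurrence"
MUTUAL_EXCLUSIVITY = "Mutual exclusivity"
NONE = "none"


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 alteration counts for one gene pair plus derived statistics."""

    gene_a: str
    gene_b: str
    neither: int
    a_not_b: int
    b_not_a: int
    both: int
    odds_ratio: float  # may be inf
    log2_odds_ratio: float
    log2_display: str
    p: float
    q: float = float("nan")
    tendency: str = NONE

    @property
    def total(self) -> int:
        return self.neither + self.a_not_b + self.b_not_a + self.both


def read_alteration_matrix(path: str | Path) -> pd.DataFrame:
    """Read a samples-by-genes binary TSV whose first column is ``sample_id``."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError(f"alteration matrix {path} contains non-binary entries")
    return df.astype(np.int8)


def contingency(matrix: pd.DataFrame, gene_a: str, gene_b: str) -> tuple[int, int, int, int]:
    """Counts (neither, a_not_b, b_not_a, both) over samples; sums to n_samples."""
    for g in (gene_a, gene_b):
        if g not in matrix.columns:
            raise KeyError(f"gene {g!r} is not a column of the alteration matrix")
    a = matrix[gene_a].to_numpy().astype(bool)
    b = matrix[gene_b].to_numpy().astype(bool)
    both = int((a & b).sum())
    a_not_b = int((a & ~b).sum())
    b_not_a = int((~a & b).sum())
    neither = int((~a & ~b).sum())
    return neither, a_not_b, b_not_a, both


def _display(log2_or: float) -> str:
    if log2_or > LOG2_DISPLAY_CAP:
        return ">3"
    if log2_or < -LOG2_DISPLAY_CAP:
        return "<-3"
    return f"{log2_or:.3f}"


def pair_stats(
    counts: tuple[int, int, int, int],
    gene_a: str = "A",
    gene_b: str = "B",
    sidedness: str = "one-sided",
    haldane: bool = False,
) -> ContingencyResult:
    """Odds ratio, log2 OR (with capped display), Fisher p and tendency for one pair.

    ``counts`` is (neither, a_not_b, b_not_a, both).  The default test is
    one-sided toward the observed direction; ``sidedness='two-sided'`` is
    available.  ``haldane`` applies the +0.5 continuity correction to the
    odds ratio (only relevant for zero-cell tables; the p-value always uses
    the raw counts).
    """
    neither, a_not_b, b_not_a, both = counts
    if min(counts) < 0:
        raise ValueError(f"contingency counts must be nonnegative, got {counts}")
    if haldane:
        n0, ab, ba, b2 = (c + 0.5 for c in counts)
        odds_ratio = (b2 * n0) / (ab * ba)
    elif a_not_b * b_not_a == 0:
        odds_ratio = math.inf if both * neither > 0 else math.nan
    else:
        odds_ratio = (both * neither) / (a_not_b * b_not_a)

    if math.isnan(odds_ratio):
        log2_or = math.nan
    elif odds_ratio == 0:
        log2_or = -math.inf
    else:
        log2_or = math.log2(odds_ratio)

    table = [[both, a_not_b], [b_not_a, neither]]
    if sidedness == "two-sided":
        alternative = "two-sided"
    elif sidedness == "one-sided":
        alternative = "less" if (not math.isnan(odds_ratio) and odds_ratio < 1) else "greater"
    else:
        raise ValueError(f"sidedness must be 'one-sided' or 'two-sided', got {sidedness!r}")
    p = float(fisher_exact(table, alternative=alternative)[1])

    if math.isnan(odds_ratio) or odds_ratio == 1:
        tendency = NONE
    elif odds_ratio > 1:
        tendency = CO_OCCURRENCE
    else:
        tendency = MUTUAL_EXCLUSIVITY

    return ContingencyResult(
        gene_a=gene_a,
        gene_b=gene_b,
        neither=neither,
        a_not_b=a_not_b,
        b_not_a=b_not_a,
        both=both,
        odds_ratio=odds_ratio,
        log2_odds_ratio=log2_or,
        log2_display=">3" if math.isinf(log2_or) and log2_or > 0 else _display(log2_or),
        p=p,
        tendency=tendency,
    )


def all_pairs(
    matrix: pd.DataFrame,
    gene_list: list[str] | None = None,
    sidedness: str = "one-sided",
) -> pd.DataFrame:
    """Contingency statistics for every unordered gene pair, BH-adjusted.

    Returns one row per pair, columns mirroring the cBioPortal result table
    (counts, log2 OR with capped display, p, q, tendency), sorted by p.
    """
    genes = list(matrix.columns) if gene_list is None else list(gene_list)
    if len(genes) < 2:
        raise ValueError("need at least two genes for pairwise statistics")
    results = []
    for ga, gb in itertools.combinations(genes, 2):
        counts = contingency(matrix, ga, gb)
        results.append(pair_stats(counts, gene_a=ga, gene_b=gb, sidedness=sidedness))
    q = bh_adjust([r.p for r in results])
    rows = [
        {
            "gene_a": r.gene_a,
            "gene_b": r.gene_b,
            "neither": r.neither,
            "a_not_b": r.a_not_b,
            "b_not_a": r.b_not_a,
            "both": r.both,
            "odds_ratio": r.odds_ratio,
            "log2_odds_ratio": r.log2_odds_ratio,
            "log2_display": r.log2_display,
            "p": r.p,
            "q": float(qi),
            "tendency": r.tendency,
        }
        for r, qi in zip(results, q)
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["p", "gene_a", "gene_b"], kind="mergesort")
        .reset_index(drop=True)
    )
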