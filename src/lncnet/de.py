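"""Differential-expression table I/O, significance filtering and biotype classification.

Consumes DESeq2-style result tables (one row per transcript, with a BH-adjusted
q-value in ``padj``), applies a joint significance filter on q and linear fold
change, and partitions the significant transcripts into lncRNA / mRNA / other
classes by ENSEMBL biotype.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns a DE results table must provide.  ``baseMean`` is optional.
REQUIRED_DE_COLUMNS = ("transcript_id", "symbol", "biotype", "log2FoldChange", "pvalue", "padj")

#: ENSEMBL biotypes conventionally treated as lncRNA classes.
DEFAULT_LNCRNA_BIOTYPES = frozenset(
    {
        "antisense",
        "lincRNA",
        "lncRNA",
        "sense_intronic",
        "sense_overlapping",
        "processed_transcript",
        "bidirectional_promoter_lncRNA",
        "3prime_overlapping_ncRNA",
        "macro_lncRNA",
    }
)

MRNA_BIOTYPE = "protein_coding"


class DEFormatError(ValueError):
    """A DE table does not conform to the expected DESeq2-results dialect."""


@dataclass(frozen=True)
class FilterSpec:
    """Joint significance threshold: BH-adjusted q and linear fold change.

    The fold-change threshold is expressed on the linear (ratio) scale and is
    applied to the magnitude of the signed log2 fold change as
    ``|log2fc| >= log2(linear_fc_min)``.  Both comparisons are inclusive.
    """

    q_max: float = 0.1
    linear_fc_min: float = 1.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_max <= 1.0):
            raise ValueError(f"q_max must lie in [0, 1], got {self.q_max}")
        if self.linear_fc_min < 1.0:
            raise ValueError(f"linear_fc_min must be >= 1, got {self.linear_fc_min}")

    @property
    def log2_fc_min(self) -> float:
        return float(np.log2(self.linear_fc_min))


@dataclass
class ContrastResult:
    """Significant transcripts of one contrast, partitioned by biotype class."""

    label: str
    significant: pd.DataFrame
    lncrnas: pd.DataFrame
    mrnas: pd.DataFrame
    other: pd.DataFrame
    biotype_composition: dict[str, float] = field(default_factory=dict)

    @property
    def lncrna_ids(self) -> set[str]:
        return set(self.lncrnas["transcript_id"])

    @property
    def mrna_ids(self) -> set[str]:
        return set(self.mrnas["transcript_id"])


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a DESeq2-style TSV of differential-expression results.

    Rows with missing ``pvalue`` or ``padj`` (DESeq2 independent filtering
    emits NA) are retained but marked non-testable via the ``testable``
    column; they can never pass a significance filter.

    Raises
    ------
    DEFormatError
        If a required column is absent (the message names the column).
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "symbol": str, "biotype": str})
    for col in REQUIRED_DE_COLUMNS:
        if col not in df.columns:
            raise DEFormatError(f"DE table {path} is missing required column {col!r}")
    if df["transcript_id"].duplicated().any():
        dups = df.loc[df["transcript_id"].duplicated(), "transcript_id"].head(3).tolist()
        raise DEFormatError(f"duplicate transcript_id values in {path}: {dups} ...")
    df["symbol"] = df["symbol"].fillna("")
    df["testable"] = df["pvalue"].notna() & df["padj"].notna()
    return df


def filter_significant(records: pd.DataFrame, spec: FilterSpec) -> pd.DataFrame:
    """Return records with ``padj <= q_max`` and ``|log2fc| >= log2(linear_fc_min)``.

    Both boundaries are inclusive.  Non-testable records (NA p or q) never
    pass.  The returned frame carries a ``direction`` column ('up'/'down')
    derived from the sign of the log2 fold change.
    """
    testable = records["testable"] if "testable" in records.columns else (
        records["pvalue"].notna() & records["padj"].notna()
    )
    mask = (
        testable
        & (records["padj"] <= spec.q_max)
        & (records["log2FoldChange"].abs() >= spec.log2_fc_min)
    )
    out = records.loc[mask].copy()
    out["direction"] = np.where(out["log2FoldChange"] >= 0, "up", "down")
    return out


def classify_biotypes(
    significant: pd.DataFrame,
    label: str = "",
    lncrna_biotypes: Iterable[str] = DEFAULT_LNCRNA_BIOTYPES,
) -> ContrastResult:
    """Partition significant transcripts into lncRNA / mRNA / other classes.

    ``biotype_composition`` reports, over the lncRNA class only, the
    proportion of each lncRNA biotype (e.g. antisense vs lincRNA); it is
    empty when no lncRNAs are present.
    """
    lnc_set = set(lncrna_biotypes)
    is_lnc = significant["biotype"].isin(lnc_set)
    is_mrna = significant["biotype"] == MRNA_BIOTYPE
    lnc = significant.loc[is_lnc]
    mrna = significant.loc[is_mrna]
    other = significant.loc[~is_lnc & ~is_mrna]
    if len(other):
        logger.info(
            "%s: %d significant transcripts fall outside lncRNA/protein_coding biotypes",
            label or "contrast", len(other),
        )
    composition: dict[str, float] = {}
    if len(lnc):
        counts = lnc["biotype"].value_counts()
        composition = {bt: float(c) / float(len(lnc)) for bt, c in counts.items()}
    return ContrastResult(
        label=label,
        significant=significant,
        lncrnas=lnc,
        mrnas=mrna,
        other=other,
        biotype_composition=composition,
    )


def load_biotype_list(path: str | Path) -> frozenset[str]:
    """Read a plain-text biotype list (one biotype per line, '#' comments)."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return frozenset(out)


def overlap_contrasts(id_sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Exact inclusion-exclusion partition of >= 2 labelled ID sets.

    Returns one row per non-empty region of the Venn partition, with the
    membership pattern, the exact IDs and the count.  Region counts sum to
    the size of the union.
    """
    if len(id_sets) < 2:
        raise ValueError("overlap_contrasts requires at least two contrasts")
    labels = list(id_sets)
    rows = []
    for pattern in itertools.product((True, False), repeat=len(labels)):
        if not any(pattern):
            continue
        region = set.intersection(*(id_sets[l] for l, i in zip(labels, pattern) if i))
        region -= set.union(*[id_sets[l] for l, i in zip(labels, pattern) if not i], set())
        rows.append(
            {
                "region": "&".join(l for l, i in zip(labels, pattern) if i)
                + ("" if all(pattern) else " only" if sum(pattern) == 1 else ""),
                **{f"in_{l}": i for l, i in zip(labels, pattern)},
                "count": len(region),
                "ids": sorted(region),
            }
        )
    return pd.DataFrame(rows)
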