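"""Hypergeometric over-representation analysis against GMT gene-set collections.

For a query gene set of size n drawn from a universe of N genes, the overlap
k with a gene set of size K is tested against the hypergeometric upper tail
P(X >= k); Benjamini-Hochberg adjustment runs across all sets of one
collection.  A pathway overlay restricts a regulatory network to the mRNAs
of one pathway, mapping which lncRNAs reach which pathway genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .network import RegulatoryNetwork

logger = logging.getLogger(__name__)


class GMTFormatError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets plus the enrichment universe.

    The default universe is the union of all member genes; callers may pass
    an explicit universe (e.g. all network mRNAs) — the choice materially
    changes p-values, so it is recorded on the results.
    """

    sets: dict[str, tuple[str, set[str]]]  # name -> (description, members)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*(m for _, m in self.sets.values()), set())
        # harmonize: members outside the universe cannot contribute to k or K
        self.sets = {
            name: (desc, members & self.universe) for name, (desc, members) in self.sets.items()
        }

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, tuple[str, set[str]]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise GMTFormatError(f"{path}:{ln}: expected name, description and >=1 member")
        name, desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
        if name in sets:
            raise GMTFormatError(f"{path}:{ln}: duplicate gene-set name {name!r}")
        sets[name] = (desc, set(members))
    return GeneSetCollection(sets=sets, universe=universe or set())


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(query: set[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation of a query gene set.

    Query genes outside the universe are dropped (count logged).  Results
    carry (k, n, K, N, p, q) per set, BH-adjusted across the collection and
    sorted by p then set name.
    """
    if not collection.universe:
        raise ValueError("enrichment universe is empty")
    inside = set(query) & collection.universe
    dropped = len(set(query)) - len(inside)
    if dropped:
        logger.info("dropped %d query genes outside the universe", dropped)
    if not inside:
        logger.warning("empty query after harmonization; returning no results")
        return pd.DataFrame(columns=["set_name", "description", "k", "n", "K", "N", "p", "q"])
    N, n = len(collection.universe), len(inside)
    rows = []
    for name, (desc, members) in collection.sets.items():
        K = len(members)
        k = len(inside & members)
        p = float(hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        rows.append({"set_name": name, "description": desc, "k": k, "n": n, "K": K, "N": N, "p": p})
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)


@dataclass
class PathwayOverlay:
    pathway_name: str
    lncrna_to_genes: dict[str, set[str]]
    edges: pd.DataFrame  # lncrna, gene, gene_direction, pathway

    @property
    def participating_lncrna_count(self) -> int:
        return len(self.lncrna_to_genes)

    @property
    def targeted_gene_count(self) -> int:
        return len(set().union(*self.lncrna_to_genes.values(), set()))


def overlay(
    network: RegulatoryNetwork,
    pathway_name: str,
    pathway_genes: set[str],
    lncrna_subset: list[str] | None = None,
) -> PathwayOverlay:
    """Restrict the network to one pathway's genes (and optionally some lncRNAs).

    Reports which lncRNAs target which pathway genes, e.g. which of the
    top-ranked regulators reach antigen-processing genes.
    """
    if not pathway_genes:
        raise ValueError("pathway gene set is empty")
    lncs = network.lncrna_ids if lncrna_subset is None else set(lncrna_subset) & network.lncrna_ids
    mapping: dict[str, set[str]] = {}
    rows = []
    for lnc in sorted(lncs):
        hit = set(network.graph.neighbors(lnc)) & pathway_genes
        if not hit:
            continue
        mapping[lnc] = hit
        for gene in sorted(hit):
            rows.append(
                {
                    "lncrna": lnc,
                    "gene": gene,
                    "gene_direction": network.graph.nodes[gene].get("direction", ""),
                    "pathway": pathway_name,
                }
            )
    edges = pd.DataFrame(rows, columns=["lncrna", "gene", "gene_direction", "pathway"])
    return PathwayOverlay(pathway_name=pathway_name, lncrna_to_genes=mapping, edges=edges)
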