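"""Bipartite lncRNA-mRNA regulatory network: construction, degree ranking, export.

The network is the intersection of an interaction-prediction table (e.g.
LongHorn-style lncRNA->mRNA predictions for TCGA PRAD) with the significant
lncRNA and mRNA sets of one differential-expression contrast.  Degree
centrality — the number of distinct mRNA targets a lncRNA retains after
the intersection — ranks the lncRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .de import ContrastResult

logger = logging.getLogger(__name__)

INTERACTION_COLUMNS = ("lncrna_id", "mrna_id")
DEFAULT_MODE = "regulates"


class NetworkFormatError(ValueError):
    pass


@dataclass
class RegulatoryNetwork:
    """Strictly bipartite graph over significant lncRNAs and their significant targets.

    ``graph`` is an undirected networkx graph whose nodes carry ``kind``
    ('lncRNA' or 'mRNA') and ``direction`` ('up'/'down', copied from the DE
    sign) attributes; edges carry ``mode``.  lncRNAs with no surviving edge
    are not represented.
    """

    graph: nx.Graph

    @property
    def lncrna_ids(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "lncRNA"}

    @property
    def mrna_ids(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "mRNA"}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, lncrna_id: str) -> int:
        return self.graph.degree(lncrna_id)


def read_interaction_table(path: str | Path) -> pd.DataFrame:
    """Read a lncRNA->mRNA interaction prediction TSV.

    Columns: ``lncrna_id``, ``mrna_id`` and optionally ``mode`` (the
    predicted regulatory mechanism, e.g. decoy / co-factor; carried as an
    opaque attribute).  Duplicate (lncrna, mrna) rows are deduplicated —
    degree counts distinct targets, not prediction rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in INTERACTION_COLUMNS:
        if col not in df.columns:
            raise NetworkFormatError(f"interaction table {path} is missing column {col!r}")
    if "mode" not in df.columns:
        df["mode"] = DEFAULT_MODE
    df["mode"] = df["mode"].fillna(DEFAULT_MODE)
    n0 = len(df)
    df = df.drop_duplicates(subset=["lncrna_id", "mrna_id"], keep="first").reset_index(drop=True)
    if len(df) < n0:
        logger.info("deduplicated %d repeated interaction rows", n0 - len(df))
    return df


def build_network(contrast: ContrastResult, interactions: pd.DataFrame) -> RegulatoryNetwork:
    """Intersect predictions with the significant DE sets of one contrast.

    Keeps exactly the edges whose lncRNA is significantly DE (lncRNA biotype)
    and whose mRNA is significantly DE (protein_coding).  lncRNAs and mRNAs
    with no surviving edge are dropped.
    """
    lnc_ids = contrast.lncrna_ids
    mrna_ids = contrast.mrna_ids
    kept = interactions[
        interactions["lncrna_id"].isin(lnc_ids) & interactions["mrna_id"].isin(mrna_ids)
    ]
    direction = {}
    for df in (contrast.lncrnas, contrast.mrnas):
        if "direction" in df.columns:
            direction.update(zip(df["transcript_id"], df["direction"]))

    g = nx.Graph()
    for lnc, mrna, mode in kept[["lncrna_id", "mrna_id", "mode"]].itertuples(index=False):
        if lnc not in g:
            g.add_node(lnc, kind="lncRNA", direction=direction.get(lnc, ""))
        if mrna not in g:
            g.add_node(mrna, kind="mRNA", direction=direction.get(mrna, ""))
        g.add_edge(lnc, mrna, mode=mode)
    return RegulatoryNetwork(graph=g)


def rank_by_centrality(network: RegulatoryNetwork, top_k: int = 11) -> pd.DataFrame:
    """Rank lncRNAs by distinct-target degree, descending.

    Ties break lexicographically on the lncRNA ID.  All lncRNAs are
    returned; the leading ``top_k`` carry ``in_top_k=True``.
    """
    rows = sorted(
        ((lnc, network.degree(lnc)) for lnc in network.lncrna_ids),
        key=lambda t: (-t[1], t[0]),
    )
    if top_k > len(rows):
        logger.warning("top_k=%d exceeds the %d ranked lncRNAs; flagging all", top_k, len(rows))
    df = pd.DataFrame(rows, columns=["lncrna_id", "degree"])
    df["rank"] = range(1, len(df) + 1)
    df["direction"] = [network.graph.nodes[l].get("direction", "") for l in df["lncrna_id"]]
    df["in_top_k"] = df["rank"] <= top_k
    df["chromosome_band"] = ""
    return df


def target_sets(network: RegulatoryNetwork) -> dict[str, set[str]]:
    """Map each lncRNA to its set of distinct mRNA targets."""
    return {lnc: set(network.graph.neighbors(lnc)) for lnc in network.lncrna_ids}


def unique_targets_by_direction(network: RegulatoryNetwork) -> dict[str, int]:
    """Count mRNA targets regulated by exactly one lncRNA, split by DE direction."""
    counts = {"up": 0, "down": 0}
    for mrna in network.mrna_ids:
        if network.graph.degree(mrna) == 1:
            d = network.graph.nodes[mrna].get("direction", "")
            if d in counts:
                counts[d] += 1
    return counts


def annotate_locations(ranked: pd.DataFrame, band_table: pd.DataFrame) -> pd.DataFrame:
    """Left-join cytogenetic bands onto a ranked lncRNA table.

    ``band_table`` needs columns ``id`` and ``band``; duplicated IDs keep the
    first occurrence.  lncRNAs absent from the table keep an empty band.
    """
    out = ranked.copy()
    if band_table.empty:
        return out
    if band_table["id"].duplicated().any():
        logger.warning("band table has duplicate IDs; keeping first occurrence")
        band_table = band_table.drop_duplicates(subset="id", keep="first")
    mapping = dict(zip(band_table["id"], band_table["band"]))
    out["chromosome_band"] = [mapping.get(l, "") for l in out["lncrna_id"]]
    missing = int((out["chromosome_band"] == "").sum())
    if missing:
        logger.info("%d ranked lncRNAs have no chromosome band annotation", missing)
    return out


def export_edges(network: RegulatoryNetwork, path: str | Path, format: str = "TSV") -> None:
    """Write the edge list as Cytoscape SIF or as an attribute-carrying TSV."""
    fmt = format.upper()
    path = Path(path)
    edges = sorted(
        (l, m) if network.graph.nodes[l]["kind"] == "lncRNA" else (m, l)
        for l, m in network.graph.edges
    )
    if fmt == "SIF":
        with open(path, "w") as fh:
            for lnc, mrna in edges:
                mode = network.graph.edges[lnc, mrna].get("mode", DEFAULT_MODE)
                fh.write(f"{lnc}\t{mode}\t{mrna}\n")
    elif fmt == "TSV":
        rows = []
        for lnc, mrna in edges:
            rows.append(
                {
                    "lncrna_id": lnc,
                    "mrna_id": mrna,
                    "mode": network.graph.edges[lnc, mrna].get("mode", DEFAULT_MODE),
                    "lncrna_direction": network.graph.nodes[lnc].get("direction", ""),
                    "mrna_direction": network.graph.nodes[mrna].get("direction", ""),
                }
            )
        pd.DataFrame(
            rows,
            columns=["lncrna_id", "mrna_id", "mode", "lncrna_direction", "mrna_direction"],
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {format!r}; use 'SIF' or 'TSV'")


def import_edges(path: str | Path) -> RegulatoryNetwork:
    """Rebuild a network from an attribute TSV written by :func:`export_edges`."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_node(row.lncrna_id, kind="lncRNA", direction=row.lncrna_direction)
        g.add_node(row.mrna_id, kind="mRNA", direction=row.mrna_direction)
        g.add_edge(row.lncrna_id, row.mrna_id, mode=row.mode)
    return RegulatoryNetwork(graph=g)
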