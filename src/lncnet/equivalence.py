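"""Structural equivalence of lncRNAs by shared mRNA targets.

Two regulators are structurally equivalent when their target sets overlap
strongly.  Pairwise set similarity (Jaccard by default) feeds hierarchical
clustering (UPGMA on 1 - similarity) and threshold-graph group extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, leaves_list
from scipy.spatial.distance import squareform
from skbio import TreeNode

logger = logging.getLogger(__name__)

METRICS = ("jaccard", "cosine", "dice")
LINKAGES = ("average", "complete", "single")


@dataclass
class SimilarityMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, unit diagonal, entries in [0, 1]
    metric: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_long(self) -> pd.DataFrame:
        """Heatmap-ready long format: one row per unordered off-diagonal pair."""
        rows = [
            (self.ids[i], self.ids[j], float(self.values[i, j]))
            for i in range(len(self.ids))
            for j in range(i + 1, len(self.ids))
        ]
        return pd.DataFrame(rows, columns=["id1", "id2", "similarity"])


@dataclass
class EquivalenceGroup:
    member_ids: list[str]
    mean_within_similarity: float
    shared_target_core: set[str]


def _pair_similarity(a: set[str], b: set[str], metric: str) -> float:
    if not a or not b:
        return 0.0
    inter = len(a & b)
    if metric == "jaccard":
        return inter / len(a | b)
    if metric == "dice":
        return 2.0 * inter / (len(a) + len(b))
    if metric == "cosine":
        return inter / float(np.sqrt(len(a) * len(b)))
    raise ValueError(f"unknown similarity metric {metric!r}; use one of {METRICS}")


def similarity(target_sets: dict[str, set[str]], metric: str = "jaccard") -> SimilarityMatrix:
    """Pairwise target-set similarity over all lncRNAs, in sorted ID order.

    Pairs where either set is empty score 0; the diagonal is fixed at 1.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown similarity metric {metric!r}; use one of {METRICS}")
    ids = sorted(target_sets)
    n = len(ids)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = _pair_similarity(target_sets[ids[i]], target_sets[ids[j]], metric)
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(ids=ids, values=values, metric=metric)


def cluster(sim: SimilarityMatrix, method: str = "average") -> np.ndarray:
    """Hierarchical clustering of the distance matrix 1 - similarity.

    Returns a scipy linkage matrix; leaf order is deterministic for a given
    matrix.  Fewer than two items yield a trivial empty linkage.
    """
    if method not in LINKAGES:
        raise ValueError(f"unknown linkage {method!r}; use one of {LINKAGES}")
    n = len(sim.ids)
    if n < 2:
        logger.warning("clustering requested for %d item(s); returning trivial tree", n)
        return np.empty((0, 4))
    dist = 1.0 - sim.values
    np.fill_diagonal(dist, 0.0)
    return linkage(squareform(dist, checks=False), method=method)


def leaf_order(sim: SimilarityMatrix, method: str = "average") -> list[str]:
    Z = cluster(sim, method)
    if not len(Z):
        return list(sim.ids)
    return [sim.ids[i] for i in leaves_list(Z)]


def to_newick(sim: SimilarityMatrix, method: str = "average") -> str:
    """Export the dendrogram as a Newick string (branch lengths in distance units)."""
    Z = cluster(sim, method)
    if not len(Z):
        return f"({','.join(sim.ids)});" if sim.ids else "();"
    tree = TreeNode.from_linkage_matrix(Z, sim.ids)
    return str(tree).strip()


def extract_groups(
    sim: SimilarityMatrix,
    target_sets: dict[str, set[str]],
    threshold: float = 0.5,
) -> list[EquivalenceGroup]:
    """Structurally equivalent groups as threshold-graph connected components.

    Builds the graph whose edges are pairs with similarity >= threshold and
    returns its connected components of size >= 2, each with the
    intersection of its members' target sets as the shared core.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    g = nx.Graph()
    g.add_nodes_from(sim.ids)
    n = len(sim.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if sim.values[i, j] >= threshold:
                g.add_edge(sim.ids[i], sim.ids[j])
    idx = {x: i for i, x in enumerate(sim.ids)}
    groups = []
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        members = sorted(comp)
        pair_sims = [
            sim.values[idx[a], idx[b]]
            for k, a in enumerate(members)
            for b in members[k + 1 :]
        ]
        core = set.intersection(*(set(target_sets.get(m, set())) for m in members))
        groups.append(
            EquivalenceGroup(
                member_ids=members,
                mean_within_similarity=float(np.mean(pair_sims)),
                shared_target_core=core,
            )
        )
    groups.sort(key=lambda g: g.member_ids)
    return groups


def most_similar_pair(
    sim: SimilarityMatrix, restrict_to: list[str] | None = None
) -> tuple[str, str, float]:
    """The off-diagonal argmax pair; ties break lexicographically on the sorted pair."""
    ids = sim.ids if restrict_to is None else [i for i in sim.ids if i in set(restrict_to)]
    if len(ids) < 2:
        raise ValueError("most_similar_pair needs at least two lncRNAs")
    idx = {x: i for i, x in enumerate(sim.ids)}
    best: tuple[str, str, float] | None = None
    for k, a in enumerate(sorted(ids)):
        for b in sorted(ids)[k + 1 :]:
            s = float(sim.values[idx[a], idx[b]])
            if best is None or s > best[2]:
                best = (a, b, s)
    assert best is not None
    return best
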