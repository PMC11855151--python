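"""Set-similarity, UPGMA clustering against a naive oracle, group extraction."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet

from lncnet import equivalence as eq


def test_similarity_identity_disjoint_and_jaccard():
    sets = {"a": {"x", "y", "z"}, "b": {"x", "y", "z"}, "c": {"q"}, "d": set()}
    sim = eq.similarity(sets)
    m = sim.to_frame()
    assert m.loc["a", "b"] == 1.0            # identical nonempty sets
    assert m.loc["a", "c"] == 0.0            # disjoint
    assert m.loc["a", "d"] == 0.0            # empty-set pair defined as 0
    assert np.allclose(np.diag(sim.values), 1.0)
    assert np.allclose(sim.values, sim.values.T)


def test_jaccard_dice_cosine_values():
    sets = {"a": {"a", "b", "c"}, "b": {"b", "c", "d"}}
    assert eq.similarity(sets, "jaccard").values[0, 1] == pytest.approx(2 / 4)
    assert eq.similarity(sets, "dice").values[0, 1] == pytest.approx(2 * 2 / 6)
    assert eq.similarity(sets, "cosine").values[0, 1] == pytest.approx(2 / 3)
    with pytest.raises(ValueError, match="metric"):
        eq.similarity(sets, "euclidean")


def test_two_item_cluster_single_merge():
    sets = {"a": {"x", "y"}, "b": {"y", "z"}}
    sim = eq.similarity(sets)
    Z = eq.cluster(sim)
    assert Z.shape == (1, 4)
    assert Z[0, 2] == pytest.approx(1 - 1 / 3)


def _naive_upgma_cophenetic(dist):
    """Brute-force UPGMA: cluster-pair distance is the mean of original
    pairwise distances; returns the cophenetic distance matrix."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph


def test_cluster_agrees_with_naive_agglomerative_oracle(rng):
    for n in (3, 5, 8):
        for _ in range(3):
            sim_vals = rng.uniform(0, 1, size=(n, n))
            sim_vals = (sim_vals + sim_vals.T) / 2
            np.fill_diagonal(sim_vals, 1.0)
            sim = eq.SimilarityMatrix(ids=[f"i{k}" for k in range(n)], values=sim_vals, metric="jaccard")
            Z = eq.cluster(sim, "average")
            got = cophenet(Z)
            dist = 1 - sim_vals
            np.fill_diagonal(dist, 0)
            expect = _naive_upgma_cophenetic(dist)
            from scipy.spatial.distance import squareform
            np.testing.assert_allclose(got, squareform(expect), atol=1e-10)


def test_planted_blocks_form_clades(small_config, interaction_bundle):
    inter, truth = interaction_bundle
    sets = inter.groupby("lncrna_id")["mrna_id"].apply(set).to_dict()
    members = {m for b in truth.equivalence_blocks for m in b}
    sim = eq.similarity({k: sets[k] for k in members})
    groups = eq.extract_groups(sim, sets, threshold=0.5)
    assert sorted(g.member_ids for g in groups) == sorted(truth.equivalence_blocks)


def test_extract_groups_trivial_cases():
    sets = {"a": {"x"}, "b": {"y"}}
    sim = eq.similarity(sets)
    assert eq.extract_groups(sim, sets, threshold=1.0) == []

    sets2 = {"a": {"x", "y", "q"}, "b": {"x", "y", "z"}}
    sim2 = eq.similarity(sets2)  # jaccard 2/4 = 0.5
    groups = eq.extract_groups(sim2, sets2, threshold=0.5)
    assert len(groups) == 1
    assert groups[0].member_ids == ["a", "b"]
    assert groups[0].shared_target_core == {"x", "y"}
    with pytest.raises(ValueError):
        eq.extract_groups(sim2, sets2, threshold=0.0)


def test_group_extraction_monotone_in_threshold(rng):
    """Lowering the threshold never splits an existing group."""
    ids = [f"i{k}" for k in range(12)]
    vals = rng.uniform(0, 1, (12, 12))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 1.0)
    sim = eq.SimilarityMatrix(ids=ids, values=vals, metric="jaccard")
    sets = {i: {i} for i in ids}
    for hi, lo in [(0.9, 0.6), (0.6, 0.3)]:
        high_groups = eq.extract_groups(sim, sets, hi)
        low_groups = eq.extract_groups(sim, sets, lo)
        for g in high_groups:
            assert any(set(g.member_ids) <= set(l.member_ids) for l in low_groups)


def test_most_similar_pair_brute_force(rng):
    ids = [f"i{k}" for k in range(10)]
    vals = rng.uniform(0, 1, (10, 10))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 1.0)
    sim = eq.SimilarityMatrix(ids=ids, values=vals, metric="jaccard")
    a, b, s = eq.most_similar_pair(sim)
    brute = max(
        ((ids[i], ids[j], vals[i, j]) for i in range(10) for j in range(i + 1, 10)),
        key=lambda t: t[2],
    )
    assert (a, b, s) == brute

    with pytest.raises(ValueError):
        eq.most_similar_pair(sim, restrict_to=["i0"])
    a2, b2, s2 = eq.most_similar_pair(sim, restrict_to=["i0", "i1", "i2"])
    assert {a2, b2} <= {"i0", "i1", "i2"}


def test_duplicate_target_sets_are_the_top_pair():
    sets = {"a": {"x", "y"}, "b": {"x", "y"}, "c": {"z"}}
    sim = eq.similarity(sets)
    assert eq.most_similar_pair(sim) == ("a", "b", 1.0)


def test_newick_export_covers_all_leaves():
    sets = {"a": {"x", "y"}, "b": {"x", "y", "z"}, "c": {"q"}}
    nwk = eq.to_newick(eq.similarity(sets))
    for leaf in sets:
        assert leaf in nwk
    assert nwk.endswith(";")


def test_permutation_invariance_of_similarity():
    sets = {"a": {"x", "y"}, "b": {"y", "z"}, "c": {"x", "z", "w"}}
    s1 = eq.similarity(sets)
    s2 = eq.similarity(dict(reversed(list(sets.items()))))
    assert s1.ids == s2.ids
    np.testing.assert_array_equal(s1.values, s2.values)
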