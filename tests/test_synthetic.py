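"""Generator contracts: determinism, planted structure, calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from lncnet import synthetic
from lncnet.de import DEFAULT_LNCRNA_BIOTYPES
from lncnet.enrichment import bh_adjust
from lncnet.synthetic import ConfigurationError, SimulationConfig


def test_empty_table_for_zero_transcripts():
    df, truth = synthetic.simulate_de_table(SimulationConfig(
        n_transcripts=0, n_significant=0, n_hub_lncrnas=0, hub_degree=1,
        background_degree_max=0, n_equivalence_blocks=0,
    ))
    assert df.empty
    assert not truth.significant_ids


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_transcripts=10, n_significant=20)
    with pytest.raises(ConfigurationError):
        SimulationConfig(hub_degree=5, background_degree_max=5)
    with pytest.raises(ConfigurationError):
        SimulationConfig(lncrna_fraction=1.5)
    with pytest.raises(ConfigurationError):
        SimulationConfig(planted_pair_odds_ratio=0)


def test_seed_determinism(small_config, de_bundle, interaction_bundle):
    de_df, _ = de_bundle
    de2, t2 = synthetic.simulate_de_table(small_config, "test")
    pd.testing.assert_frame_equal(de_df, de2)
    inter, _ = interaction_bundle
    inter2, _ = synthetic.simulate_interaction_table(small_config, de2, t2)
    pd.testing.assert_frame_equal(inter, inter2)
    alt1, _ = synthetic.simulate_alteration_matrix(small_config)
    alt2, _ = synthetic.simulate_alteration_matrix(small_config)
    pd.testing.assert_frame_equal(alt1, alt2)


def test_planted_significance_recovered_at_thresholds(de_bundle, small_config):
    """Counting rows at (q<=0.1, |log2FC|>=log2 1.5) on the emitted table
    recovers the planted count up to Beta-tail detection noise.

    Signal p ~ Beta(a, 1) passes a BH p-cutoff t with probability t^a; with
    the cutoff near q_max * n_significant / n_transcripts = 0.01 the
    detection rate is 0.01^0.05 ~= 0.79, so the expected recovered count is
    ~79 with binomial sd ~4; the band below is +-4 sd around that.
    """
    de_df, truth = de_bundle
    passed = de_df[(de_df.padj <= 0.1) & (de_df.log2FoldChange.abs() >= math.log2(1.5))]
    detect = (0.1 * small_config.n_significant / small_config.n_transcripts) ** small_config.signal_beta_a
    expected = small_config.n_significant * detect
    sd = math.sqrt(small_config.n_significant * detect * (1 - detect))
    assert expected - 4 * sd <= len(passed) <= expected + 4 * sd + 5
    # all recovered-significant rows are planted (false positives are rare)
    assert len(set(passed.transcript_id) - set(truth.significant_ids)) <= 5
    lnc_frac = passed.biotype.isin(DEFAULT_LNCRNA_BIOTYPES).mean()
    assert abs(lnc_frac - small_config.lncrna_fraction) < 0.12


def test_planted_ids_exist_in_tables(de_bundle, interaction_bundle, full_truth):
    de_df, _ = de_bundle
    inter, _ = interaction_bundle
    ids = set(de_df.transcript_id)
    assert set(full_truth.significant_ids) <= ids
    assert set(full_truth.hub_ids) <= ids
    for block in full_truth.equivalence_blocks:
        assert set(block) <= ids
    edge_ids = set(inter.lncrna_id) | set(inter.mrna_id)
    assert set(full_truth.hub_ids) <= edge_ids


def test_hub_degree_planted_exactly(small_config, interaction_bundle):
    inter, truth = interaction_bundle
    degrees = inter.groupby("lncrna_id").size()
    for hub in truth.hub_ids:
        assert degrees[hub] == small_config.hub_degree
    non_hub = degrees.drop(truth.hub_ids)
    assert (non_hub <= small_config.background_degree_max + 1).all()


def test_full_overlap_block_has_identical_target_sets():
    cfg = SimulationConfig(
        n_transcripts=500, n_significant=80, lncrna_fraction=0.3,
        n_hub_lncrnas=1, hub_degree=20, n_equivalence_blocks=1, block_size=3,
        block_target_overlap=1.0, seed=3,
    )
    de_df, t = synthetic.simulate_de_table(cfg)
    inter, t2 = synthetic.simulate_interaction_table(cfg, de_df, t)
    sets = inter.groupby("lncrna_id")["mrna_id"].apply(set)
    a, b, c = t2.equivalence_blocks[0]
    assert sets[a] == sets[b] == sets[c]


def test_hub_degree_error_when_pool_too_small():
    cfg = SimulationConfig(
        n_transcripts=100, n_significant=20, lncrna_fraction=0.5,
        n_hub_lncrnas=1, hub_degree=50, n_equivalence_blocks=0,
    )
    de_df, t = synthetic.simulate_de_table(cfg)
    with pytest.raises(ConfigurationError, match="hub_degree"):
        synthetic.simulate_interaction_table(cfg, de_df, t)


def test_unique_edges(interaction_bundle):
    inter, _ = interaction_bundle
    assert not inter.duplicated(subset=["lncrna_id", "mrna_id"]).any()


def test_joint_bernoulli_closed_form():
    # independence
    assert synthetic.joint_bernoulli_cell(0.2, 0.3, 1.0) == pytest.approx(0.06)
    # a solved cell reproduces the requested odds ratio exactly
    for theta in (0.25, 2.0, 16.0):
        p11 = synthetic.joint_bernoulli_cell(0.02, 0.02, theta)
        p10 = p01 = 0.02 - p11
        p00 = 1 - p11 - p10 - p01
        assert (p11 * p00) / (p10 * p01) == pytest.approx(theta, rel=1e-9)
        assert 0.0 <= p11 <= 0.02


def test_alteration_matrix_zero_rate_all_zero():
    cfg = SimulationConfig(alteration_base_rate=0.0, n_samples=100, seed=1)
    df, _ = synthetic.simulate_alteration_matrix(cfg)
    assert (df.to_numpy() == 0).all()


def test_alteration_matrix_neutral_pair_or_near_one():
    cfg = SimulationConfig(
        planted_pair_odds_ratio=1.0, n_samples=50_000,
        alteration_base_rate=0.05, seed=11,
    )
    df, truth = synthetic.simulate_alteration_matrix(cfg)
    a, b, _ = truth.co_altered_pairs[0]
    x, y = df[a].to_numpy().astype(bool), df[b].to_numpy().astype(bool)
    n11 = int((x & y).sum()); n10 = int((x & ~y).sum())
    n01 = int((~x & y).sum()); n00 = int((~x & ~y).sum())
    or_hat = (n11 * n00) / (n10 * n01)
    assert abs(or_hat - 1.0) < 0.25


def test_alteration_matrix_planted_or_16():
    cfg = SimulationConfig(planted_pair_odds_ratio=16.0, n_samples=50_000, seed=5)
    df, truth = synthetic.simulate_alteration_matrix(cfg)
    a, b, theta = truth.co_altered_pairs[0]
    x, y = df[a].to_numpy().astype(bool), df[b].to_numpy().astype(bool)
    or_hat = ((x & y).sum() * (~x & ~y).sum()) / ((x & ~y).sum() * (~x & y).sum())
    assert abs(np.log2(or_hat) - np.log2(theta)) < 0.15


def test_null_calibration_bh():
    """With no planted signals, the BH q<=0.1 pass fraction stays near or
    below the nominal level across replicates (FDR control under
    independence; with all-null p-values rejections are rare)."""
    fractions = []
    for seed in range(20):
        cfg = SimulationConfig(
            n_transcripts=500, n_significant=0, n_hub_lncrnas=0, hub_degree=1,
            background_degree_max=0, n_equivalence_blocks=0, seed=seed,
        )
        df, _ = synthetic.simulate_de_table(cfg)
        fractions.append((df.padj <= 0.1).mean())
    assert np.mean(fractions) <= 0.1 * 1.1


def test_gene_sets_planted_membership(small_config, full_truth):
    coll, set_truth = synthetic.make_gene_sets(small_config, full_truth)
    assert len(coll) == small_config.n_gene_sets
    assert len(set_truth.enriched_set_names) == small_config.n_hub_lncrnas
    for name, hub in zip(sorted(set_truth.enriched_set_names), sorted(full_truth.hub_targets)):
        _, members = coll.sets[name]
        overlap = members & set(full_truth.hub_targets[hub])
        assert len(overlap) >= small_config.planted_enriched_set_overlap
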