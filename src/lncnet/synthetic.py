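"""Synthetic pipeline inputs with planted, recoverable ground truth.

Every downstream stage consumes one of four inputs: a DESeq2-style
differential-expression table, a lncRNA->mRNA interaction prediction table,
GMT gene-set collections, and a binary sample-by-gene alteration matrix.
This module emulates all four with known planted structure — significant
transcripts, hub regulators, structurally equivalent blocks, enriched gene
sets and co-altered gene pairs — so each stage's output can be checked
against a ground truth rather than against another tool.

Planted signal p-values are drawn from Beta(0.05, 1), which concentrates
mass near zero strongly enough that Benjamini-Hochberg at q <= 0.1 recovers
essentially all planted signals; null p-values are Uniform(0, 1).

Co-altered pairs are simulated from the 2x2 joint Bernoulli distribution
whose marginals equal the base alteration rate and whose population odds
ratio equals the requested value, solved in closed form (Plackett copula
cell probability), so the planted odds ratio is exact rather than
approximate.

Every generator is a pure function of its configuration: the same seed
yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection, bh_adjust

LNCRNA_BIOTYPE_PROBS = {
    "antisense": 0.48,
    "lincRNA": 0.44,
    "sense_intronic": 0.05,
    "processed_transcript": 0.03,
}
OTHER_BIOTYPE_PROBS = {"protein_coding": 0.92, "processed_pseudogene": 0.08}
EDGE_MODES = ("decoy", "co-factor", "multi-functional")

# rng stream tags so each generator is independently deterministic
_STREAM_DE, _STREAM_NET, _STREAM_ALT, _STREAM_SETS = 1, 2, 3, 4


class ConfigurationError(ValueError):
    """A simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe a down-scaled cohort: 5,000 transcripts of which a
    quarter are lncRNA biotypes, 500 planted significant transcripts with
    strong effects (mean |log2 FC| = 2), a handful of hub regulators whose
    degree well exceeds the background, small structurally equivalent
    blocks with 90% within-block target overlap, 500 gene sets of which a
    few are enriched by construction, and a 5,000-sample alteration matrix
    with a 2% base alteration rate and one planted co-altered pair at odds
    ratio 16.
    """

    n_transcripts: int = 5000
    lncrna_fraction: float = 0.25
    n_significant: int = 500
    effect_log2fc_mean: float = 2.0
    effect_log2fc_sd: float = 0.5
    signal_beta_a: float = 0.05
    n_hub_lncrnas: int = 3
    hub_degree: int = 50
    background_degree_max: int = 10
    n_equivalence_blocks: int = 3
    block_size: int = 3
    block_target_overlap: float = 0.9
    n_gene_sets: int = 500
    planted_enriched_set_overlap: int = 20
    n_samples: int = 5000
    alteration_base_rate: float = 0.02
    planted_pair_odds_ratio: float = 16.0
    n_alteration_genes: int = 10
    n_planted_pairs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_transcripts", "n_significant", "n_hub_lncrnas", "hub_degree",
            "background_degree_max", "n_equivalence_blocks", "block_size",
            "n_gene_sets", "planted_enriched_set_overlap", "n_samples",
            "n_alteration_genes", "n_planted_pairs",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        for name in ("lncrna_fraction", "block_target_overlap", "alteration_base_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_significant > self.n_transcripts:
            raise ConfigurationError(
                f"n_significant={self.n_significant} exceeds n_transcripts={self.n_transcripts}"
            )
        if self.hub_degree <= self.background_degree_max:
            raise ConfigurationError("hub_degree must exceed background_degree_max")
        if self.planted_pair_odds_ratio <= 0:
            raise ConfigurationError("planted_pair_odds_ratio must be positive")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators; every ID exists in the emitted tables."""

    significant_ids: list[str] = field(default_factory=list)
    significant_lncrna_ids: list[str] = field(default_factory=list)
    significant_mrna_ids: list[str] = field(default_factory=list)
    hub_ids: list[str] = field(default_factory=list)
    hub_targets: dict[str, list[str]] = field(default_factory=dict)
    equivalence_blocks: list[list[str]] = field(default_factory=list)
    enriched_set_names: list[str] = field(default_factory=list)
    co_altered_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def merge(self, other: "PlantedTruth") -> "PlantedTruth":
        merged = PlantedTruth()
        for f in dataclasses.fields(PlantedTruth):
            mine, theirs = getattr(self, f.name), getattr(other, f.name)
            if isinstance(mine, dict):
                setattr(merged, f.name, {**mine, **theirs})
            else:
                setattr(merged, f.name, mine + [x for x in theirs if x not in mine])
        return merged

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["co_altered_pairs"] = [list(t) for t in self.co_altered_pairs]
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        payload = json.loads(Path(path).read_text())
        payload["co_altered_pairs"] = [tuple(t) for t in payload.get("co_altered_pairs", [])]
        return cls(**payload)


def _transcript_id(i: int) -> str:
    return f"ENSG{i:011d}"


def simulate_de_table(
    config: SimulationConfig, contrast_label: str = "synthetic"
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Emit a DESeq2-style results table with planted significant transcripts.

    Exactly ``round(n_significant * lncrna_fraction)`` of the planted
    signals are lncRNA biotypes and the rest protein-coding, so the
    downstream filter recovers a lncRNA/mRNA split matching the configured
    fraction.  q is computed by Benjamini-Hochberg over all p-values, so the
    number of rows passing (q <= 0.1, |log2FC| >= log2 1.5) equals the
    planted count up to the Beta-tail detection noise.
    """
    rng = np.random.default_rng([config.seed, _STREAM_DE])
    n = config.n_transcripts
    truth = PlantedTruth()
    columns = [
        "transcript_id", "symbol", "biotype", "baseMean", "log2FoldChange", "pvalue", "padj",
    ]
    if n == 0:
        return pd.DataFrame(columns=columns), truth

    ids = [_transcript_id(i) for i in range(n)]
    n_lnc = int(round(n * config.lncrna_fraction))
    lnc_mask = np.zeros(n, dtype=bool)
    lnc_mask[rng.choice(n, size=n_lnc, replace=False)] = True

    biotypes = np.empty(n, dtype=object)
    lnc_bts, lnc_ps = zip(*LNCRNA_BIOTYPE_PROBS.items())
    oth_bts, oth_ps = zip(*OTHER_BIOTYPE_PROBS.items())
    biotypes[lnc_mask] = rng.choice(lnc_bts, size=n_lnc, p=lnc_ps)
    biotypes[~lnc_mask] = rng.choice(oth_bts, size=n - n_lnc, p=oth_ps)

    symbols = [
        (f"LNC{i:05d}" if lnc_mask[i] else f"PCG{i:05d}") for i in range(n)
    ]

    # plant significants: lncRNA share matches the configured fraction,
    # the remainder drawn from protein-coding transcripts
    n_sig_lnc = int(round(config.n_significant * config.lncrna_fraction))
    n_sig_mrna = config.n_significant - n_sig_lnc
    lnc_idx = np.flatnonzero(lnc_mask)
    pc_idx = np.flatnonzero(biotypes == "protein_coding")
    if n_sig_lnc > len(lnc_idx) or n_sig_mrna > len(pc_idx):
        raise ConfigurationError(
            "not enough lncRNA or protein_coding transcripts to plant the requested signals"
        )
    sig_lnc = rng.choice(lnc_idx, size=n_sig_lnc, replace=False)
    sig_mrna = rng.choice(pc_idx, size=n_sig_mrna, replace=False)
    sig_idx = np.concatenate([sig_lnc, sig_mrna]).astype(int)
    sig_mask = np.zeros(n, dtype=bool)
    sig_mask[sig_idx] = True

    p = rng.uniform(0.0, 1.0, size=n)
    p[sig_mask] = rng.beta(config.signal_beta_a, 1.0, size=len(sig_idx))
    q = bh_adjust(p)

    log2fc = rng.normal(0.0, 0.3, size=n)
    mag = np.abs(rng.normal(config.effect_log2fc_mean, config.effect_log2fc_sd, size=len(sig_idx)))
    mag = np.maximum(mag, math.log2(1.5))  # planted effects always clear the FC filter
    log2fc[sig_idx] = rng.choice([-1.0, 1.0], size=len(sig_idx)) * mag

    base_mean = np.exp(rng.normal(5.0, 2.0, size=n))

    df = pd.DataFrame(
        {
            "transcript_id": ids,
            "symbol": symbols,
            "biotype": biotypes,
            "baseMean": base_mean,
            "log2FoldChange": log2fc,
            "pvalue": p,
            "padj": q,
        }
    )
    truth.significant_ids = [ids[i] for i in sorted(sig_idx)]
    truth.significant_lncrna_ids = [ids[i] for i in sorted(sig_lnc)]
    truth.significant_mrna_ids = [ids[i] for i in sorted(sig_mrna)]
    return df, truth


def simulate_interaction_table(
    config: SimulationConfig, de_table: pd.DataFrame, de_truth: PlantedTruth
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Emit a lncRNA->mRNA prediction table with planted hubs and equivalence blocks.

    Construction over the significant mRNA pool:

    * structural roles (hubs, block members) go to the planted lncRNAs with
      the smallest p-values, so the ground truth deterministically survives
      the downstream BH significance filter (BH rejection is a p-threshold);
    * each hub receives exactly ``hub_degree`` significant targets (sampled
      independently, so hub-hub target overlap stays far below the group
      threshold);
    * each equivalence block reserves a disjoint slice of the smallest-p
      significant mRNAs: a shared core covering ``block_target_overlap`` of
      each member's targets plus one member-private target each;
    * remaining significant lncRNAs receive small mutually disjoint slices
      of significant targets, in ascending-p order (the weakest receive
      none and drop out of the network, as real intersection filtering
      does);
    * every non-structural lncRNA, significant or not, is padded with
      non-significant targets so the raw table is much larger than the
      intersected network.
    """
    rng = np.random.default_rng([config.seed, _STREAM_NET])
    truth = PlantedTruth()
    pmap = dict(zip(de_table["transcript_id"], de_table["pvalue"]))
    by_p = lambda ids: sorted(ids, key=lambda t: (pmap.get(t, 1.0), t))  # noqa: E731
    sig_lnc = by_p(de_truth.significant_lncrna_ids)
    sig_mrna = by_p(de_truth.significant_mrna_ids)
    if config.n_hub_lncrnas and config.hub_degree > len(sig_mrna):
        raise ConfigurationError(
            f"hub_degree={config.hub_degree} exceeds the {len(sig_mrna)} significant mRNAs"
        )
    need_lnc = config.n_hub_lncrnas + config.n_equivalence_blocks * config.block_size
    if need_lnc > len(sig_lnc):
        raise ConfigurationError(
            f"{need_lnc} planted lncRNAs requested but only {len(sig_lnc)} are significant"
        )

    hubs = sig_lnc[: config.n_hub_lncrnas]
    block_members = sig_lnc[config.n_hub_lncrnas : need_lnc]
    background = sig_lnc[need_lnc:]

    edges: dict[str, set[str]] = {}

    # equivalence blocks: disjoint slices of the strongest significant mRNAs
    block_degree = max(config.background_degree_max, 2)
    core_size = int(math.ceil(config.block_target_overlap * block_degree))
    per_block = core_size + config.block_size  # core + one private target per member
    blocks: list[list[str]] = []
    if config.n_equivalence_blocks * per_block > len(sig_mrna):
        raise ConfigurationError("significant mRNA pool too small for the requested blocks")
    cursor = 0
    for b in range(config.n_equivalence_blocks):
        slice_ = sig_mrna[cursor : cursor + per_block]
        cursor += per_block
        core = slice_[:core_size]
        privates = slice_[core_size:]
        members = block_members[b * config.block_size : (b + 1) * config.block_size]
        for m, priv in zip(members, privates):
            edges[m] = set(core) | ({priv} if core_size < block_degree else set())
        blocks.append(sorted(members))
    truth.equivalence_blocks = blocks

    # hubs: independent samples over the full significant pool
    for h in hubs:
        edges[h] = set(rng.choice(sig_mrna, size=config.hub_degree, replace=False))
    truth.hub_ids = sorted(hubs)
    truth.hub_targets = {h: sorted(edges[h]) for h in hubs}

    # background: small mutually disjoint slices; the weakest get none
    remaining = sig_mrna[cursor:]
    bg_degree = min(config.background_degree_max, 3)
    for i, lnc in enumerate(background):
        lo = i * bg_degree
        if lo >= len(remaining):
            break
        edges.setdefault(lnc, set()).update(remaining[lo : lo + bg_degree])

    # pad non-structural lncRNAs (incl. non-significant) with non-significant targets
    structural = set(hubs) | set(block_members)
    all_lnc = de_table.loc[
        de_table["biotype"].isin(LNCRNA_BIOTYPE_PROBS), "transcript_id"
    ].tolist()
    nonsig_mrna = de_table.loc[
        (de_table["biotype"] == "protein_coding")
        & ~de_table["transcript_id"].isin(set(de_truth.significant_ids)),
        "transcript_id",
    ].to_numpy()
    if len(nonsig_mrna):
        for lnc in all_lnc:
            if lnc in structural:
                continue
            cap = int(rng.integers(1, config.background_degree_max + 1))
            extra = max(cap - len(edges.get(lnc, ())), 0)
            if extra:
                picks = rng.choice(nonsig_mrna, size=min(extra, len(nonsig_mrna)), replace=False)
                edges.setdefault(lnc, set()).update(picks)

    rows = [
        {"lncrna_id": lnc, "mrna_id": m, "mode": EDGE_MODES[rng.integers(len(EDGE_MODES))]}
        for lnc in sorted(edges)
        for m in sorted(edges[lnc])
    ]
    return pd.DataFrame(rows, columns=["lncrna_id", "mrna_id", "mode"]), truth


def joint_bernoulli_cell(p_a: float, p_b: float, odds_ratio: float) -> float:
    """P(A=1, B=1) for the 2x2 Bernoulli with given marginals and odds ratio.

    Plackett's closed form: for theta != 1 the (1,1) cell is the admissible
    root of a quadratic in p11; for theta = 1 it is the independence product.
    """
    if odds_ratio == 1.0:
        return p_a * p_b
    t = odds_ratio
    s = 1.0 + (p_a + p_b) * (t - 1.0)
    disc = s * s - 4.0 * t * (t - 1.0) * p_a * p_b
    if disc < 0:
        raise ConfigurationError("no admissible joint distribution for these rates and OR")
    p11 = (s - math.sqrt(disc)) / (2.0 * (t - 1.0))
    lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
    if not (lo - 1e-12 <= p11 <= hi + 1e-12):
        raise ConfigurationError(
            f"joint cell probability {p11:.4g} outside [{lo:.4g}, {hi:.4g}] "
            f"for rates ({p_a}, {p_b}) at OR {odds_ratio}"
        )
    return min(max(p11, lo), hi)


def simulate_alteration_matrix(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Binary sample-by-gene alteration matrix with planted co-altered pairs.

    The first ``2 * n_planted_pairs`` genes form pairs drawn from the joint
    Bernoulli whose marginals equal ``alteration_base_rate`` and whose
    population odds ratio equals ``planted_pair_odds_ratio``; all other
    genes are independent Bernoulli at the base rate.
    """
    if config.n_samples < 1 and config.n_alteration_genes:
        raise ConfigurationError("n_samples must be >= 1")
    if 2 * config.n_planted_pairs > config.n_alteration_genes:
        raise ConfigurationError("not enough alteration genes for the requested planted pairs")
    rng = np.random.default_rng([config.seed, _STREAM_ALT])
    truth = PlantedTruth()
    genes = [f"ALT{g:04d}" for g in range(config.n_alteration_genes)]
    n = config.n_samples
    rate = config.alteration_base_rate
    data = np.zeros((n, len(genes)), dtype=np.int8)

    for k in range(config.n_planted_pairs):
        ia, ib = 2 * k, 2 * k + 1
        p11 = joint_bernoulli_cell(rate, rate, config.planted_pair_odds_ratio)
        p10 = rate - p11
        p01 = rate - p11
        p00 = 1.0 - p11 - p10 - p01
        cells = rng.choice(4, size=n, p=[p00, p10, p01, p11])
        data[:, ia] = (cells == 1) | (cells == 3)
        data[:, ib] = (cells == 2) | (cells == 3)
        truth.co_altered_pairs.append((genes[ia], genes[ib], config.planted_pair_odds_ratio))

    rest = slice(2 * config.n_planted_pairs, None)
    n_rest = len(genes) - 2 * config.n_planted_pairs
    if n_rest:
        data[:, rest] = rng.random((n, n_rest)) < rate

    df = pd.DataFrame(data, columns=genes)
    df.insert(0, "sample_id", [f"S{i:06d}" for i in range(n)])
    return df.set_index("sample_id"), truth


def make_gene_sets(
    config: SimulationConfig, truth: PlantedTruth
) -> tuple[GeneSetCollection, PlantedTruth]:
    """Gene-set collection over the significant mRNA universe with planted enrichment.

    One planted set per hub contains ``planted_enriched_set_overlap`` of
    that hub's targets (plus random filler), so the hub's target set is
    over-represented in it by construction; the remaining sets are random
    draws from the universe.
    """
    rng = np.random.default_rng([config.seed, _STREAM_SETS])
    universe = set(truth.significant_mrna_ids)
    out = PlantedTruth()
    sets: dict[str, tuple[str, set[str]]] = {}
    if not universe:
        return GeneSetCollection(sets={}, universe=set()), out

    uni = sorted(universe)
    for h, hub in enumerate(sorted(truth.hub_targets)):
        targets = truth.hub_targets[hub]
        k = min(config.planted_enriched_set_overlap, len(targets))
        members = set(rng.choice(targets, size=k, replace=False))
        filler = rng.choice(uni, size=min(10, len(uni)), replace=False)
        members |= set(filler)
        name = f"PLANTED_{h:02d}_{hub}"
        sets[name] = (f"planted enriched set for hub {hub}", members)
        out.enriched_set_names.append(name)

    n_random = max(config.n_gene_sets - len(sets), 0)
    for s in range(n_random):
        size = int(rng.integers(10, 51))
        members = set(rng.choice(uni, size=min(size, len(uni)), replace=False))
        sets[f"SET_{s:04d}"] = (f"random set {s}", members)
    return GeneSetCollection(sets=sets, universe=universe), out


# ---------------------------------------------------------------------------
# TSV writers

def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_interaction_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_alteration_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="sample_id")
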