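"""Configuration-driven orchestration of the full analysis for one or more contrasts.

The run report mirrors the analysis narrative as a chain of counts: DE
transcripts -> significant -> lncRNA/mRNA split -> network lncRNAs and
edges -> top-ranked regulators -> equivalence groups -> enriched sets
(-> co-occurrence table), plus the cross-contrast overlap when two or more
contrasts are configured.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import cooccurrence as cooc
from . import de, enrichment, equivalence, network, synthetic

logger = logging.getLogger(__name__)

try:
    __version__ = version("lncnet")
except PackageNotFoundError:  # pragma: no cover - only outside an install
    __version__ = "unknown"


class ContrastConfig(BaseModel):
    label: str
    de_table: Path
    q_max: float = 0.1
    linear_fc_min: float = 1.5

    @field_validator("q_max")
    @classmethod
    def _q_range(cls, v: float) -> float:
        if not 0 <= v <= 1:
            raise ValueError("q_max must lie in [0, 1]")
        return v


class PipelineConfig(BaseModel):
    """Validated YAML-backed configuration for a full run.

    The significance thresholds default to the stringent contrast
    (q <= 0.1, linear FC >= 1.5); relaxed contrasts (e.g. small-cohort
    supplementation comparisons at q <= 0.4) override them per contrast.
    """

    contrasts: list[ContrastConfig]
    interaction_table: Path
    gene_sets: dict[str, Path] = Field(default_factory=dict)
    alteration_matrix: Optional[Path] = None
    band_table: Optional[Path] = None
    lncrna_biotypes: Optional[Path] = None
    similarity_metric: str = "jaccard"
    equivalence_threshold: float = 0.5
    top_k: int = 11
    universe_policy: str = "collection"  # or "network_mrnas"
    output_dir: Path = Path("lncnet_out")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls.model_validate(payload)


class StageError(RuntimeError):
    """An orchestrated stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:16]


def synth(config: synthetic.SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a full synthetic input bundle plus its planted truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    de_df, de_truth = synthetic.simulate_de_table(config, "synthetic")
    inter_df, net_truth = synthetic.simulate_interaction_table(config, de_df, de_truth)
    alt_df, alt_truth = synthetic.simulate_alteration_matrix(config)
    truth = de_truth.merge(net_truth).merge(alt_truth)
    collection, set_truth = synthetic.make_gene_sets(config, truth)
    truth = truth.merge(set_truth)

    paths = {
        "de_table": out / "de_table.tsv",
        "interaction_table": out / "interactions.tsv",
        "alteration_matrix": out / "alterations.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "planted_truth.json",
    }
    synthetic.write_de_table(de_df, paths["de_table"])
    synthetic.write_interaction_table(inter_df, paths["interaction_table"])
    synthetic.write_alteration_matrix(alt_df, paths["alteration_matrix"])
    enrichment.write_gmt(collection, paths["gene_sets"])
    truth.to_json(paths["truth"])
    return paths


def run(config: PipelineConfig) -> dict:
    """Execute every stage for each contrast and write a machine-readable report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": "lncnet",
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "contrasts": {},
    }

    interactions = _stage("interactions")(network.read_interaction_table)(
        config.interaction_table
    )
    biotypes = (
        de.load_biotype_list(config.lncrna_biotypes)
        if config.lncrna_biotypes
        else de.DEFAULT_LNCRNA_BIOTYPES
    )
    band_table = (
        pd.read_csv(config.band_table, sep="\t", dtype=str)
        if config.band_table
        else pd.DataFrame(columns=["id", "band"])
    )

    lnc_sets: dict[str, set[str]] = {}
    for contrast in config.contrasts:
        report["contrasts"][contrast.label] = _run_contrast(
            contrast, config, interactions, biotypes, band_table, out
        )
        lnc_sets[contrast.label] = set(
            report["contrasts"][contrast.label]["significant_lncrna_ids"]
        )

    if len(config.contrasts) >= 2:
        overlap = _stage("overlap")(de.overlap_contrasts)(lnc_sets)
        overlap.to_csv(out / "lncrna_overlap.tsv", sep="\t", index=False)
        report["lncrna_overlap"] = {
            row["region"]: row["count"] for _, row in overlap.iterrows()
        }
        inter_all = set.intersection(*lnc_sets.values())
        report["n_lncrnas_overlapping_all_contrasts"] = len(inter_all)

    if config.alteration_matrix is not None:
        matrix = _stage("cooccurrence")(cooc.read_alteration_matrix)(
            config.alteration_matrix
        )
        pairs = _stage("cooccurrence")(cooc.all_pairs)(matrix)
        pairs.to_csv(out / "cooccurrence.tsv", sep="\t", index=False)
        report["cooccurrence"] = {
            "n_pairs": len(pairs),
            "top_pairs": pairs.head(10).to_dict(orient="records"),
        }

    report_path = out / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return report


def _run_contrast(
    contrast: ContrastConfig,
    config: PipelineConfig,
    interactions: pd.DataFrame,
    biotypes: frozenset[str],
    band_table: pd.DataFrame,
    out: Path,
) -> dict:
    label = contrast.label
    records = _stage("read_de")(de.read_de_table)(contrast.de_table)
    spec = de.FilterSpec(q_max=contrast.q_max, linear_fc_min=contrast.linear_fc_min)
    significant = _stage("filter")(de.filter_significant)(records, spec)
    result = _stage("classify")(de.classify_biotypes)(significant, label, biotypes)

    net = _stage("network")(network.build_network)(result, interactions)
    ranked = _stage("rank")(network.rank_by_centrality)(net, config.top_k)
    ranked = network.annotate_locations(ranked, band_table)
    ranked.to_csv(out / f"{label}.ranked_lncrnas.tsv", sep="\t", index=False)
    network.export_edges(net, out / f"{label}.network.tsv", "TSV")
    network.export_edges(net, out / f"{label}.network.sif", "SIF")
    unique_dir = network.unique_targets_by_direction(net)

    tsets = network.target_sets(net)
    sim = _stage("equivalence")(equivalence.similarity)(tsets, config.similarity_metric)
    groups = equivalence.extract_groups(sim, tsets, config.equivalence_threshold)
    sim.to_long().to_csv(out / f"{label}.similarity.tsv", sep="\t", index=False)
    if len(sim.ids) >= 2:
        (out / f"{label}.dendrogram.nwk").write_text(equivalence.to_newick(sim))

    enriched_summary = {}
    network_mrnas = net.mrna_ids
    query = network_mrnas
    for coll_name, gmt_path in config.gene_sets.items():
        universe = network_mrnas if config.universe_policy == "network_mrnas" else None
        collection = _stage("enrichment")(enrichment.read_gmt)(gmt_path, universe)
        results = _stage("enrichment")(enrichment.ora)(query, collection)
        results.to_csv(out / f"{label}.{coll_name}.enrichment.tsv", sep="\t", index=False)
        enriched_summary[coll_name] = results.head(10)[
            ["set_name", "k", "n", "K", "N", "p", "q"]
        ].to_dict(orient="records")

    struct_lncrnas = sorted({m for g in groups for m in g.member_ids})
    return {
        "n_records": len(records),
        "filter": {"q_max": contrast.q_max, "linear_fc_min": contrast.linear_fc_min},
        "n_significant_transcripts": len(significant),
        "n_significant_lncrnas": len(result.lncrnas),
        "n_significant_mrnas": len(result.mrnas),
        "biotype_composition": result.biotype_composition,
        "significant_lncrna_ids": sorted(result.lncrna_ids),
        "n_network_lncrnas": len(net.lncrna_ids),
        "n_network_mrnas": len(net.mrna_ids),
        "n_interactions": net.n_edges,
        "n_uniquely_regulated_up": unique_dir["up"],
        "n_uniquely_regulated_down": unique_dir["down"],
        "top_ranked": ranked.loc[
            ranked["in_top_k"], ["lncrna_id", "degree", "rank", "direction", "chromosome_band"]
        ].to_dict(orient="records"),
        "n_equivalence_groups": len(groups),
        "n_structurally_equivalent_lncrnas": len(struct_lncrnas),
        "structurally_equivalent_lncrnas": struct_lncrnas,
        "top_enriched_sets": enriched_summary,
    }
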