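"""End-to-end orchestration: classify -> annotate -> tag -> enrich (+ methdiff).

Each stage logs conserved row counts (read = emitted + skipped) and every
stochastic step draws from the single configured seed, so a rerun with the
same config produces identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import io
from .annotation import annotate_frame, build_gene_index, build_region_index
from .classifier import classify_frame, summarize_classes
from .enrichment import (
    StratumScheme,
    assign_strata,
    category_enrichment,
    feasible_index,
    fit_enrichment_model,
    matched_simulation_test,
)
from .errors import ConfigError
from .ld import LdIndex, annotate_proxies, ld_prune
from .methylation import bin_nearby, find_cgmuts

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.  Flag overrides win over YAML."""

    snps: str
    ld: str
    outcomes: str
    out_dir: str
    islands: Optional[str] = None
    genes: Optional[str] = None
    normal: Optional[str] = None
    tumor: Optional[str] = None
    mutations: Optional[str] = None
    tag_r2: float = 0.8
    prune_r2: Tuple[float, ...] = (0.8,)
    shore_width: int = 2000
    promoter_width: int = 2000
    n_draws: int = 300
    index_size: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for r2 in (self.tag_r2, *self.prune_r2):
            if not (0.0 <= r2 <= 1.0):
                raise ConfigError(f"r2 threshold {r2} outside [0, 1]")
        if self.shore_width < 0 or self.promoter_width < 0:
            raise ConfigError("region widths must be >= 0")
        if self.n_draws <= 0 or self.index_size <= 0:
            raise ConfigError("n_draws and index_size must be positive")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "prune_r2" in raw and not isinstance(raw["prune_r2"], tuple):
            raw["prune_r2"] = tuple(
                raw["prune_r2"] if isinstance(raw["prune_r2"], (list,)) else [raw["prune_r2"]]
            )
        return cls(**raw)


def _select_index(
    positives: pd.DataFrame,
    proxies: pd.DataFrame,
    strata: pd.Series,
    index_size: int,
) -> List[str]:
    """Top-signal index set: outcome-positive proxies ranked by reported p,
    restricted to strata whose sampling pools can match them."""
    on_panel = positives[positives["snp_id"].isin(set(proxies["snp_id"]))]
    ranked = on_panel.sort_values(["reported_p", "snp_id"]).drop_duplicates("snp_id")
    return feasible_index(ranked["snp_id"].tolist(), proxies, strata, index_size)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full enrichment pipeline and write results under ``out_dir``.

    Returns the results dict (also written as ``results.json``): per prune
    threshold, the logistic fit, the matched-simulation test on the
    top-signal index set, and per-category fits for trait outcomes; plus
    stage counts and, when methylation inputs are configured, the
    distance-binned methylation-difference summary.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": {**dataclasses.asdict(config)}, "counts": {}}

    snps, n_skipped = io.read_snp_table(config.snps)
    logger.info("classify: %d SNPs read, %d skipped", len(snps) + n_skipped, n_skipped)
    classified = classify_frame(snps)
    results["counts"]["snps_read"] = len(snps) + n_skipped
    results["counts"]["snps_skipped"] = n_skipped
    results["counts"]["by_class"] = (
        classified["cg_class"].value_counts().to_dict()
    )

    if config.islands:
        islands = io.read_bed(config.islands)
        region_index = build_region_index(islands, config.shore_width)
        gene_index = None
        if config.genes:
            genes = io.read_bed(config.genes, require_strand=True)
            gene_index = build_gene_index(genes, config.promoter_width)
        classified = annotate_frame(classified, region_index, gene_index)
        summary = summarize_classes(classified, "cpg_region")
        summary.to_csv(out_dir / "class_summary.tsv", sep="\t", index=False)
        results["class_summary"] = summary.to_dict(orient="records")
    io.write_snp_table(classified, out_dir / "classified.tsv")

    ld_pairs = io.read_ld_table(config.ld)
    ld_index = LdIndex.from_frame(ld_pairs)
    proxies_all = annotate_proxies(classified, ld_index, config.tag_r2)
    io.write_proxies(proxies_all, out_dir / "proxies.tsv")
    results["counts"]["ld_pairs"] = len(ld_pairs)
    results["counts"]["n_cgsnp"] = int(proxies_all["is_cgsnp"].sum())
    results["counts"]["n_cgsnpt"] = int(proxies_all["is_cgsnpt"].sum())

    outcomes = io.read_outcomes(config.outcomes)
    order = classified.sort_values(["chrom", "pos", "snp_id"])["snp_id"].tolist()

    results["enrichment"] = {}
    for prune_threshold in config.prune_r2:
        retained = ld_prune(order, ld_index, prune_threshold)
        proxies = proxies_all[proxies_all["snp_id"].isin(set(retained))].reset_index(
            drop=True
        )
        strata = assign_strata(proxies, StratumScheme())
        entry: dict = {"n_proxies": len(proxies)}
        for kind, group in outcomes.groupby("outcome", sort=True):
            kind_entry: dict = {}
            positive_ids = set(group["snp_id"]) & set(proxies["snp_id"])
            data = pd.DataFrame(
                {
                    "y": proxies["snp_id"].isin(positive_ids).astype(int),
                    "x_cgsnpt": proxies["is_cgsnpt"].astype(int),
                    "x_maf": proxies["maf"],
                    "x_tags": proxies["n_tagged"],
                }
            )
            kind_entry["logistic"] = fit_enrichment_model(data).as_dict()
            index_ids = _select_index(group, proxies, strata, config.index_size)
            sim = matched_simulation_test(
                index_ids,
                proxies,
                strata,
                n_draws=config.n_draws,
                seed=config.seed,
            )
            kind_entry["simulation"] = sim.as_dict()
            if kind == "trait" and group["category"].replace("", pd.NA).notna().any():
                kind_entry["by_category"] = {
                    name: res.as_dict()
                    for name, res in category_enrichment(group, proxies).items()
                }
            entry[kind] = kind_entry
        results["enrichment"][f"prune_r2_{prune_threshold:g}"] = entry

    if config.normal and config.tumor and config.mutations:
        normal = io.read_methylation_track(config.normal)
        tumor = io.read_methylation_track(config.tumor)
        muts = io.read_mutations(config.mutations)
        cgmuts = find_cgmuts(muts)
        summary = bin_nearby(cgmuts, normal, tumor)
        summary.to_csv(out_dir / "methdiff_summary.tsv", sep="\t", index=False)
        results["methylation"] = summary.to_dict(orient="records")
        results["counts"]["n_cgmuts"] = len(cgmuts)

    io.write_results_json(results, out_dir / "results.json")
    return results
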