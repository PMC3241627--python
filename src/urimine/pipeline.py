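"""End-to-end orchestration of the marker-mining workflow.

Stage order (each stage persists its output so it can be re-run or
swapped for externally produced lists):

1. differential expression per tissue and dataset, filtered at the
   configured FDR/fold-change cut-offs, datasets pooled by union;
2. tissue-exclusivity comparison; keep genes unique to the target tissue;
3. ontology filter: keep candidates carrying >= 1 controlled term
   (after true-path propagation);
4. biofluid cross-reference: flag urine/blood presence, drop candidates
   absent from urine;
5. marker-table assembly (fold change and p-value from the target
   tissue's DE results — median across that tissue's datasets);
6. gene-set enrichment, seed selection, subnetwork extraction and
   centrality-based prioritization.

The run is deterministic given the config (no stage draws random
numbers); the seed is recorded for provenance of synthetic inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from statistics import median

import pandas as pd
import yaml

from . import de as de_mod
from . import network as net_mod
from . import ontology as onto_mod
from .io import (MarkerRecord, read_annotations, read_edges, read_expression_table,
                 read_gene_list, read_gene_sets, write_gene_list, write_marker_table)
from .ontology import read_ontology_dag
from .specificity import TissueGeneSets, partition, summary_counts, unique_to

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "rank_markers",
           "summarize_fluids"]

logger = logging.getLogger("urimine.pipeline")


class ConfigError(ValueError):
    """Raised when a pipeline config fails startup validation."""


@dataclass
class PipelineConfig:
    """Paths and parameters for one end-to-end run (YAML-loadable)."""

    target_tissue: str
    expression: dict[str, list[str]]          # tissue -> dataset paths
    annotations: str
    ontology: str
    urine_roster: str
    blood_roster: str
    outdir: str
    edges: str | None = None
    gene_sets: str | None = None
    target_gene_set: str | None = None
    controlled_terms: list[str] | None = None
    min_term_frequency: float = 0.019
    de: dict = dc_field(default_factory=dict)
    fc_summary: str = "median"                # cross-dataset fold-change summary
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        stray = set(raw) - known
        if stray:
            raise ConfigError(f"unknown config keys: {sorted(stray)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.target_tissue not in self.expression:
            raise ConfigError(
                f"target tissue {self.target_tissue!r} not among input tissues "
                f"{sorted(self.expression)}")
        if len(self.expression) < 2:
            raise ConfigError("need expression data for >= 2 tissues to compare")
        paths = [p for ps in self.expression.values() for p in ps]
        paths += [self.annotations, self.ontology, self.urine_roster, self.blood_roster]
        paths += [p for p in (self.edges, self.gene_sets) if p]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise ConfigError(f"input paths do not exist: {missing}")
        if self.fc_summary not in ("median", "mean", "max"):
            raise ConfigError(f"fc_summary must be median/mean/max, got {self.fc_summary!r}")


@dataclass
class PipelineResult:
    markers: list[MarkerRecord]
    stage_counts: dict[str, int]
    centrality: pd.DataFrame
    enrichment: pd.DataFrame
    priority: list[str]
    seeds: set[str]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage; writes reports under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    de_cfg = de_mod.DEFilterConfig(**config.de) if config.de else de_mod.DEFilterConfig()

    # 1. differential expression per tissue, pooled across datasets
    up_sets: dict[str, set[str]] = {}
    target_results: list[list[de_mod.DEResult]] = []
    for tissue, paths in config.expression.items():
        per_dataset: list[set[str]] = []
        for path in paths:
            table = read_expression_table(path)
            results = de_mod.de_test(table)
            per_dataset.append(de_mod.filter_de(results, de_cfg))
            if tissue == config.target_tissue:
                target_results.append(results)
        up_sets[tissue] = de_mod.merge_dataset_lists(per_dataset)
        write_gene_list(up_sets[tissue], outdir / f"upregulated_{tissue}.txt")
        logger.info("stage de[%s]: %d up-regulated genes", tissue, len(up_sets[tissue]))
    counts["de_target_up"] = len(up_sets[config.target_tissue])

    # 2. exclusivity
    tissues = TissueGeneSets(tissues=list(config.expression), sets=up_sets)
    part = partition(tissues)
    summary_counts(part).to_csv(outdir / "exclusivity_counts.tsv", sep="\t", index=False)
    unique = unique_to(tissues, config.target_tissue)
    write_gene_list(unique, outdir / f"unique_{config.target_tissue}.txt")
    counts["unique_to_target"] = len(unique)
    logger.info("stage exclusivity: %d genes unique to %s", len(unique), config.target_tissue)

    # 3. ontology filter
    dag = read_ontology_dag(config.ontology)
    annotations = read_annotations(config.annotations)
    propagated = onto_mod.propagate_annotations(annotations, dag)
    urine = read_gene_list(config.urine_roster)
    blood = read_gene_list(config.blood_roster)
    freqs = onto_mod.term_frequencies(urine, propagated, labels=dag.names)
    controlled = onto_mod.select_controlled_terms(
        freqs, min_frequency=config.min_term_frequency, explicit=config.controlled_terms)
    fluid_candidates = onto_mod.filter_by_terms(unique, propagated, controlled)
    counts["ontology_filtered"] = len(fluid_candidates)
    logger.info("stage ontology: %d candidates carry controlled terms", len(fluid_candidates))

    # 4. fluid presence; drop candidates not present in urine
    presence = onto_mod.flag_fluid_presence(fluid_candidates, urine, blood)
    present = [p for p in presence if p.in_urine]
    counts["urine_present"] = len(present)
    logger.info("stage fluids: %d candidates present in urine", len(present))

    # 5. marker table (DE statistics from target tissue, summarized across datasets)
    stat_by_gene: dict[str, tuple[float, float]] = {}
    summarize = {"median": median, "mean": lambda xs: sum(xs) / len(xs), "max": max}
    agg = summarize[config.fc_summary]
    per_gene_fc: dict[str, list[float]] = {}
    per_gene_p: dict[str, list[float]] = {}
    for results in target_results:
        for r in results:
            per_gene_fc.setdefault(r.gene, []).append(r.fold_change)
            per_gene_p.setdefault(r.gene, []).append(r.p_value)
    for g in per_gene_fc:
        stat_by_gene[g] = (float(agg(per_gene_fc[g])), float(min(per_gene_p[g])))
    markers = [
        MarkerRecord(
            gene=p.gene, in_urine=p.in_urine, in_blood=p.in_blood,
            fold_change=stat_by_gene.get(p.gene, (1.0, 1.0))[0],
            p_value=stat_by_gene.get(p.gene, (1.0, 1.0))[1],
        )
        for p in present
    ]
    markers = rank_markers(markers, by="fold_change")
    write_marker_table(markers, outdir / "markers.tsv")
    counts["markers"] = len(markers)

    # 6. enrichment, seeds, subnetwork, centrality
    marker_genes = {m.gene for m in markers}
    enrichment_df = pd.DataFrame(
        columns=["set_name", "overlap", "set_size", "candidate_size",
                 "universe_size", "p_value", "q_value"])
    seeds: set[str] = set(marker_genes)
    if config.gene_sets and marker_genes:
        gene_sets = read_gene_sets(config.gene_sets)
        # all tissues share one platform, so one dataset defines the universe
        universe = set(read_expression_table(
            config.expression[config.target_tissue][0]).genes)
        enrichments = net_mod.hypergeometric_enrich(marker_genes, gene_sets, universe)
        enrichment_df = pd.DataFrame([vars(e) for e in enrichments])
        if config.target_gene_set:
            seeds = net_mod.select_seeds(enrichments, gene_sets, marker_genes,
                                         config.target_gene_set)
    enrichment_df.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    counts["seeds"] = len(seeds)

    edges = read_edges(config.edges) if config.edges else []
    graph = net_mod.build_graph(marker_genes, edges)
    subnet = net_mod.extract_subnetwork(graph, seeds) if seeds else graph
    scores = net_mod.centrality_scores(subnet)
    centrality_df = pd.DataFrame([vars(s) for s in scores]).sort_values(
        ["betweenness", "closeness_standard", "gene"],
        ascending=[False, False, True]).reset_index(drop=True) if scores else \
        pd.DataFrame(columns=["gene", "betweenness", "closeness_farness",
                              "closeness_standard"])
    centrality_df.to_csv(outdir / "centrality.tsv", sep="\t", index=False)
    priority = net_mod.prioritize(scores, k=min(3, len(scores))) if scores else []

    with open(outdir / "stage_counts.tsv", "w") as fh:
        for k, v in counts.items():
            fh.write(f"{k}\t{v}\n")
    return PipelineResult(markers=markers, stage_counts=counts,
                          centrality=centrality_df, enrichment=enrichment_df,
                          priority=priority, seeds=seeds)


def rank_markers(markers: list[MarkerRecord], by: str = "fold_change") -> list[MarkerRecord]:
    """Order markers by fold change (descending) or p-value (ascending),
    with the gene symbol as a stable tie-break."""
    if not markers:
        raise ValueError("marker list is empty")
    if by == "fold_change":
        return sorted(markers, key=lambda m: (-m.fold_change, m.gene))
    if by == "p_value":
        return sorted(markers, key=lambda m: (m.p_value, m.gene))
    raise ValueError(f"rank key must be fold_change or p_value, got {by!r}")


def summarize_fluids(markers: list[MarkerRecord]) -> dict[str, int]:
    """Counts of urine-only, dual-fluid and total markers."""
    both = sum(1 for m in markers if m.in_urine and m.in_blood)
    urine_only = sum(1 for m in markers if m.in_urine and not m.in_blood)
    return {"urine_only": urine_only, "both": both, "total": len(markers)}
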