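"""Ground-truth-labeled synthetic inputs for every pipeline stage.

The generator emulates the statistical structure of the real study
inputs without touching any database:

* per-tissue two-group log2 expression with planted tissue-specific
  up-regulation (Gaussian noise around a per-gene baseline);
* a reference fluid proteome roster whose propagated ontology-term
  frequencies hit configured targets (defaults: the six controlled-term
  frequencies 34.8 / 25.5 / 13.2 / 11.3 / 5.5 / 1.9 %), with the planted
  fluid genes guaranteed to carry controlled terms;
* a sparse typed interaction graph with one planted hub.

Everything is a pure function of (config, seed): the same seed yields
byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (AnnotationRecord, EdgeRecord, ExpressionTable, GeneSet,
                 write_annotations, write_edges, write_expression_table,
                 write_gene_list, write_gene_sets)
from .ontology import OntologyDAG

__all__ = ["SynthConfig", "TruthBundle", "DEFAULT_FLUID_TERM_FREQUENCIES",
           "generate_expression", "generate_ontology", "generate_network",
           "generate_bundle", "write_bundle"]

#: Controlled-term frequency targets for the synthetic fluid proteome;
#: the labels follow the published controlled-vocabulary spellings.
DEFAULT_FLUID_TERM_FREQUENCIES: dict[str, float] = {
    "Extracelluar region part": 0.348,
    "Response to stimulus": 0.255,
    "Cell adhesion": 0.132,
    "Calcium ion binding": 0.113,
    "Cell communication": 0.055,
    "Amine metabolic process": 0.019,
}

_DEFAULT_TISSUES = ("prostate", "bladder", "kidney")


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition knobs for the synthetic bundle.

    Defaults plant a log2 effect of 2 (4-fold) with sd 0.5 noise in
    10-vs-10 sample groups over 500 genes and three tissues, 30 unique
    up-regulated genes per tissue of which one third are fluid genes.
    """

    n_genes: int = 500
    n_tissues: int = 3
    samples_per_group: int = 10
    log2_effect: float = 2.0
    noise_sd: float = 0.5
    n_unique_up_per_tissue: int = 30
    n_shared_up: int = 10
    fluid_term_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FLUID_TERM_FREQUENCIES))
    fluid_gene_fraction: float = 1.0 / 3.0
    roster_size: int = 500
    blood_overlap: float = 0.5
    hub_degree: int = 5
    noise_edge_density: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_tissues", "samples_per_group",
                     "n_unique_up_per_tissue", "roster_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fluid_gene_fraction", "blood_overlap", "noise_edge_density"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        planted = self.n_unique_up_per_tissue * self.n_tissues + self.n_shared_up
        if planted > self.n_genes:
            raise ValueError(
                f"cannot plant {planted} up-regulated genes among {self.n_genes}")
        if not self.fluid_term_frequencies:
            raise ValueError("fluid_term_frequencies must be non-empty")

    @property
    def tissues(self) -> list[str]:
        names = list(_DEFAULT_TISSUES[: self.n_tissues])
        names += [f"tissue{i}" for i in range(len(names) + 1, self.n_tissues + 1)]
        return names


@dataclass
class TruthBundle:
    """The generator's planted ground truth, for recovery tests."""

    unique_up: dict[str, set[str]]
    shared_up: set[str]
    fluid_genes: set[str]
    planted_hub: str | None = None
    controlled_terms: set[str] = field(default_factory=set)

    def fluid_unique_to(self, tissue: str) -> set[str]:
        """Planted tissue-specific fluid genes — the pipeline's target."""
        return self.unique_up[tissue] & self.fluid_genes


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_expression(config: SynthConfig) -> tuple[list[ExpressionTable], TruthBundle]:
    """Per-tissue tumor-vs-normal log2 tables with planted up-regulation.

    Values = per-gene baseline N(8, 1) + log2_effect on tumor samples of
    planted genes (tissue-unique genes shift only in their tissue,
    shared genes in all tissues) + N(0, noise_sd) noise.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    order = rng.permutation(config.n_genes)
    cursor = 0
    unique_up: dict[str, set[str]] = {}
    fluid: set[str] = set()
    n_fluid = round(config.fluid_gene_fraction * config.n_unique_up_per_tissue)
    for tissue in config.tissues:
        idx = order[cursor: cursor + config.n_unique_up_per_tissue]
        cursor += config.n_unique_up_per_tissue
        tissue_genes = [genes[i] for i in idx]
        unique_up[tissue] = set(tissue_genes)
        fluid.update(tissue_genes[:n_fluid])
    shared_idx = order[cursor: cursor + config.n_shared_up]
    shared_up = {genes[i] for i in shared_idx}

    baseline = rng.normal(8.0, 1.0, size=config.n_genes)
    n = config.samples_per_group
    samples = [f"T{i + 1}" for i in range(n)] + [f"N{i + 1}" for i in range(n)]
    labels = ["tumor"] * n + ["normal"] * n
    tables = []
    for tissue in config.tissues:
        shift = np.array(
            [config.log2_effect if (g in unique_up[tissue] or g in shared_up) else 0.0
             for g in genes]
        )
        values = baseline[:, None] + rng.normal(0.0, config.noise_sd, (config.n_genes, 2 * n))
        values[:, :n] += shift[:, None]
        tables.append(ExpressionTable(genes=list(genes), samples=list(samples),
                                      labels=list(labels), values=values))
    truth = TruthBundle(unique_up=unique_up, shared_up=shared_up, fluid_genes=fluid)
    return tables, truth


def generate_ontology(
    config: SynthConfig, truth: TruthBundle
) -> tuple[OntologyDAG, list[AnnotationRecord], set[str], set[str]]:
    """Build the DAG, annotations and fluid rosters around the truth.

    The urine roster contains every planted fluid gene plus filler
    proteins up to ``roster_size``. Each configured fluid term annotates
    round(freq * roster_size) roster genes; the highest-frequency term's
    annotation set includes all fluid genes (assigned through a leaf
    child, so frequencies only come out right after propagation). Decoy
    terms annotate non-fluid genes at a frequency below every target.
    """
    rng = np.random.default_rng(config.seed + 1)
    R = config.roster_size
    fluid = sorted(truth.fluid_genes)
    if len(fluid) > R:
        raise ValueError(f"roster_size {R} smaller than {len(fluid)} fluid genes")
    targets = sorted(config.fluid_term_frequencies.items(), key=lambda kv: -kv[1])
    counts = {label: round(freq * R) for label, freq in targets}
    top_label = targets[0][0]
    if counts[top_label] < len(fluid):
        raise ValueError(
            f"top term frequency {targets[0][1]} cannot cover {len(fluid)} fluid genes "
            f"at roster size {R}")

    filler = [f"UP{i:05d}" for i in range(R - len(fluid))]
    roster = fluid + filler
    roster_set = set(roster)

    root = "biological entity"
    terms = {root}
    parents: dict[str, set[str]] = {}
    leaf_of: dict[str, str] = {}
    for label, _ in targets:
        leaf = f"{label} (leaf)"
        terms.update({label, leaf})
        parents[label] = {root}
        parents[leaf] = {label}
        leaf_of[label] = leaf
    decoys = [f"decoy process {i}" for i in range(4)]
    for d in decoys:
        terms.add(d)
        parents[d] = {root}
    dag = OntologyDAG(terms=terms, parents=parents, names={})

    annotations: list[AnnotationRecord] = []
    # top term: all fluid genes via the leaf (exercises propagation) + filler
    extra = counts[top_label] - len(fluid)
    chosen = fluid + list(rng.choice(filler, size=extra, replace=False))
    annotations += [AnnotationRecord(g, leaf_of[top_label]) for g in fluid]
    annotations += [AnnotationRecord(g, top_label) for g in chosen[len(fluid):]]
    # remaining terms: random roster members
    for label, _ in targets[1:]:
        members = rng.choice(roster, size=counts[label], replace=False)
        annotations += [AnnotationRecord(g, label) for g in members]
    # decoys annotate non-roster expression genes (the planted non-fluid
    # candidates among them must never gain a controlled term)
    non_fluid = sorted(
        set().union(*truth.unique_up.values()) - truth.fluid_genes)
    for d in decoys:
        k = min(len(non_fluid), max(1, R // 100))
        members = rng.choice(non_fluid, size=k, replace=False)
        annotations += [AnnotationRecord(g, d) for g in members]

    n_blood_shared = round(config.blood_overlap * R)
    blood_shared = rng.choice(roster, size=n_blood_shared, replace=False)
    blood = set(blood_shared) | {f"BP{i:05d}" for i in range(R // 2)}

    truth.controlled_terms = {label for label, _ in targets}
    return dag, annotations, roster_set, blood


def generate_network(config: SynthConfig, truth: TruthBundle) -> list[EdgeRecord]:
    """Star around a planted hub plus Erdős–Rényi noise among fluid genes."""
    rng = np.random.default_rng(config.seed + 2)
    markers = sorted(truth.fluid_genes)
    if config.hub_degree >= len(markers):
        raise ValueError(
            f"hub_degree {config.hub_degree} must be < {len(markers)} markers")
    hub = markers[int(rng.integers(len(markers)))]
    others = [m for m in markers if m != hub]
    spokes = list(rng.choice(others, size=config.hub_degree, replace=False))
    kinds = list(rng.choice(
        ["coexpression", "shared_domain", "colocalization", "physical"],
        size=config.hub_degree))
    edges = {EdgeRecord(hub, s, k) for s, k in zip(spokes, kinds)}
    for i, a in enumerate(markers):
        for b in markers[i + 1:]:
            if rng.random() < config.noise_edge_density:
                kind = str(rng.choice(
                    ["coexpression", "shared_domain", "colocalization", "physical"]))
                edges.add(EdgeRecord(a, b, kind))
    truth.planted_hub = hub
    return sorted(edges)


def generate_bundle(config: SynthConfig):
    """All synthetic artifacts at once.

    Returns (tables, dag, annotations, urine_roster, blood_roster,
    edges, gene_sets, truth). The ``tumor_growth`` gene set holds half of
    the target (first) tissue's fluid genes plus decoy members, so seed
    selection has something real to find.
    """
    tables, truth = generate_expression(config)
    dag, annotations, urine, blood = generate_ontology(config, truth)
    edges = generate_network(config, truth)

    rng = np.random.default_rng(config.seed + 3)
    target = config.tissues[0]
    target_fluid = sorted(truth.fluid_unique_to(target))
    half = target_fluid[: max(1, len(target_fluid) // 2)]
    all_genes = _gene_names(config.n_genes)
    decoy_members = list(rng.choice(
        sorted(set(all_genes) - set(target_fluid)), size=20, replace=False))
    gene_sets = [
        GeneSet(name="tumor_growth", description="synthetic growth/proliferation set",
                members=set(half) | set(decoy_members[:10])),
        GeneSet(name="unrelated_process", description="synthetic decoy set",
                members=set(decoy_members[10:])),
    ]
    return tables, dag, annotations, urine, blood, edges, gene_sets, truth


def write_bundle(config: SynthConfig, outdir: str | Path) -> TruthBundle:
    """Write every artifact in the dialects the readers accept.

    Produces per-tissue expression TSVs, annotation and child-parent DAG
    TSVs, one-column rosters, a typed edge list, a GMT file, a pipeline
    config YAML, and the truth sidecar TSV.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables, dag, annotations, urine, blood, edges, gene_sets, truth = generate_bundle(config)

    expression_paths: dict[str, list[str]] = {}
    for tissue, table in zip(config.tissues, tables):
        p = outdir / f"expression_{tissue}.tsv"
        write_expression_table(table, p)
        expression_paths[tissue] = [str(p)]
    write_annotations(annotations, outdir / "annotations.tsv")
    with open(outdir / "ontology.tsv", "w") as fh:
        roots = dag.terms - set(dag.parents)
        for r in sorted(roots):
            fh.write(f"{r}\t\n")
        for child in sorted(dag.parents):
            for parent in sorted(dag.parents[child]):
                fh.write(f"{child}\t{parent}\n")
    write_gene_list(urine, outdir / "urine_roster.txt")
    write_gene_list(blood, outdir / "blood_roster.txt")
    write_edges(edges, outdir / "edges.tsv")
    write_gene_sets(gene_sets, outdir / "gene_sets.gmt")

    with open(outdir / "truth.tsv", "w") as fh:
        for tissue, genes in truth.unique_up.items():
            for g in sorted(genes):
                fh.write(f"unique_up\t{tissue}\t{g}\n")
        for g in sorted(truth.shared_up):
            fh.write(f"shared_up\t-\t{g}\n")
        for g in sorted(truth.fluid_genes):
            fh.write(f"fluid_gene\t-\t{g}\n")
        fh.write(f"planted_hub\t-\t{truth.planted_hub}\n")
        for t in sorted(truth.controlled_terms):
            fh.write(f"controlled_term\t-\t{t}\n")

    pipeline_cfg = {
        "target_tissue": config.tissues[0],
        "expression": expression_paths,
        "annotations": str(outdir / "annotations.tsv"),
        "ontology": str(outdir / "ontology.tsv"),
        "urine_roster": str(outdir / "urine_roster.txt"),
        "blood_roster": str(outdir / "blood_roster.txt"),
        "edges": str(outdir / "edges.tsv"),
        "gene_sets": str(outdir / "gene_sets.gmt"),
        "target_gene_set": "tumor_growth",
        "controlled_terms": sorted(truth.controlled_terms),
        "de": {"fdr_max": 0.05, "fc_min": 2.0, "direction": "up"},
        "outdir": str(outdir / "results"),
        "seed": config.seed,
    }
    with open(outdir / "pipeline.yaml", "w") as fh:
        yaml.safe_dump(pipeline_cfg, fh, sort_keys=False)
    return truth
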