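"""Ontology-based "presence in urine" filtering.

The idea: terms that appear at high frequency among the proteins of a
reference urinary proteome (e.g. extracellular region part, response to
stimulus, cell adhesion, calcium ion binding, cell communication, amine
metabolic process) act as a controlled vocabulary for "this gene product
can end up in urine". Candidate genes carrying at least one controlled
term survive; presence is then confirmed against explicit urine/blood
protein rosters.

Annotations obey the true-path rule: a gene annotated to a term is
implicitly annotated to every ancestor, so frequencies and the filter are
always computed on the propagated closure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx

from .io import AnnotationRecord

__all__ = ["OntologyDAG", "TermFrequency", "ControlledTermSet", "FluidPresence",
           "propagate_annotations", "term_frequencies", "select_controlled_terms",
           "filter_by_terms", "flag_fluid_presence", "read_ontology_dag"]


@dataclass
class OntologyDAG:
    """A term DAG given by child -> parents relations, with optional labels."""

    terms: set[str]
    parents: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, ps in self.parents.items():
            if child not in self.terms:
                raise ValueError(f"relation child {child!r} not among terms")
            stray = ps - self.terms
            if stray:
                raise ValueError(f"parents of {child!r} not among terms: {sorted(stray)}")
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((c, p) for c, ps in self.parents.items() for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology relations contain a cycle: {cycle}")
        self._graph = g

    def ancestors(self, term: str) -> set[str]:
        """All ancestors of ``term`` (excluding the term itself)."""
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        return set(nx.descendants(self._graph, term))  # edges point child -> parent

    def label(self, term: str) -> str:
        return self.names.get(term, term)


@dataclass(frozen=True)
class TermFrequency:
    term: str
    label: str
    frequency: float

    def __post_init__(self) -> None:
        if not 0 <= self.frequency <= 1:
            raise ValueError(f"frequency out of [0, 1]: {self.frequency}")


@dataclass
class ControlledTermSet:
    """The terms selected as the presence-in-fluid filter vocabulary."""

    terms: list[TermFrequency]
    min_frequency: float = 0.0

    def __post_init__(self) -> None:
        low = [t for t in self.terms if t.frequency < self.min_frequency]
        if low:
            raise ValueError(
                f"terms below min_frequency {self.min_frequency}: {[t.term for t in low]}"
            )

    @property
    def term_ids(self) -> set[str]:
        return {t.term for t in self.terms}

    @property
    def labels(self) -> set[str]:
        return {t.label for t in self.terms}


@dataclass(frozen=True)
class FluidPresence:
    gene: str
    in_urine: bool
    in_blood: bool


def propagate_annotations(
    annotations: list[AnnotationRecord], dag: OntologyDAG
) -> set[AnnotationRecord]:
    """True-path closure: annotate every gene to all ancestors of its terms.

    Idempotent; output is a superset of the input.
    """
    closure: set[AnnotationRecord] = set()
    anc_cache: dict[str, set[str]] = {}
    for rec in annotations:
        if rec.term not in dag.terms:
            raise KeyError(f"annotation term {rec.term!r} not in ontology")
        if rec.term not in anc_cache:
            anc_cache[rec.term] = dag.ancestors(rec.term)
        closure.add(rec)
        for anc in anc_cache[rec.term]:
            closure.add(AnnotationRecord(gene=rec.gene, term=anc))
    return closure


def term_frequencies(
    roster: set[str], annotations: set[AnnotationRecord],
    labels: dict[str, str] | None = None,
) -> list[TermFrequency]:
    """Per-term fraction of roster genes annotated (post-propagation).

    Terms annotating no roster member are omitted. Sorted by descending
    frequency, then term id for determinism.
    """
    if not roster:
        raise ValueError("roster must be non-empty")
    labels = labels or {}
    counts: dict[str, set[str]] = {}
    for rec in annotations:
        if rec.gene in roster:
            counts.setdefault(rec.term, set()).add(rec.gene)
    freqs = [
        TermFrequency(term=t, label=labels.get(t, t), frequency=len(gs) / len(roster))
        for t, gs in counts.items()
    ]
    return sorted(freqs, key=lambda f: (-f.frequency, f.term))


def select_controlled_terms(
    freqs: list[TermFrequency], min_frequency: float = 0.019,
    explicit: list[str] | None = None,
) -> ControlledTermSet:
    """Select the controlled vocabulary by frequency threshold.

    ``explicit`` (term ids or labels) overrides the threshold entirely.
    An empty selection is allowed but warned about.
    """
    if explicit is not None:
        wanted = set(explicit)
        chosen = [f for f in freqs if f.term in wanted or f.label in wanted]
        missing = wanted - {f.term for f in chosen} - {f.label for f in chosen}
        if missing:
            warnings.warn(f"explicit controlled terms not found in frequencies: {sorted(missing)}",
                          stacklevel=2)
        return ControlledTermSet(terms=sorted(chosen, key=lambda f: (-f.frequency, f.term)),
                                 min_frequency=0.0)
    if not 0 < min_frequency <= 1:
        raise ValueError(f"min_frequency must be in (0, 1], got {min_frequency}")
    chosen = [f for f in freqs if f.frequency >= min_frequency]
    if not chosen:
        warnings.warn(f"no term reaches min_frequency {min_frequency}; filter is empty",
                      stacklevel=2)
    return ControlledTermSet(terms=chosen, min_frequency=min_frequency)


def filter_by_terms(
    candidates: set[str], annotations: set[AnnotationRecord],
    controlled: ControlledTermSet,
) -> set[str]:
    """Candidates annotated (after propagation) to >= 1 controlled term."""
    if not controlled.terms:
        raise ValueError("controlled term set is empty")
    wanted = controlled.term_ids | controlled.labels
    hit = {rec.gene for rec in annotations if rec.term in wanted}
    return candidates & hit


def flag_fluid_presence(
    candidates: set[str], urine_roster: set[str], blood_roster: set[str],
) -> list[FluidPresence]:
    """Cross-reference candidates against urine and blood protein rosters."""
    return [
        FluidPresence(gene=g, in_urine=g in urine_roster, in_blood=g in blood_roster)
        for g in sorted(candidates)
    ]


def read_ontology_dag(path) -> OntologyDAG:
    """Read a child<TAB>parent relation table into an :class:`OntologyDAG`.

    An optional third column carries the child's human-readable label.
    A line with an empty parent field declares a root term.
    """
    from pathlib import Path

    terms: set[str] = set()
    parents: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path} line {lineno}: expected child<TAB>parent")
        child, parent = parts[0].strip(), parts[1].strip()
        if not child:
            raise ValueError(f"{path} line {lineno}: empty child term")
        terms.add(child)
        if parent:
            terms.add(parent)
            parents.setdefault(child, set()).add(parent)
        if len(parts) >= 3 and parts[2].strip():
            names[child] = parts[2].strip()
    return OntologyDAG(terms=terms, parents=parents, names=names)
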