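"""Typed interaction graphs and centrality-based marker prioritization.

Candidate markers and their interaction partners form an undirected
graph whose edges carry one of four evidence kinds (co-expression,
shared protein domain, co-localization, physical interaction). Edge
kinds are collapsed to simple edges for centrality; they are kept on the
graph for reporting.

Two centralities drive the ranking:

* betweenness — for vertex v, sum over unordered pairs s != t != v of
  sigma_st(v) / sigma_st, shortest-path counts, unweighted, unnormalized
  (Freeman's definition);
* closeness, in two conventions: *farness*, the mean geodesic distance
  from v to the vertices reachable from it (0 for isolated vertices by
  convention), and the *standard* reciprocal form, reachable-count over
  summed distances scaled by component coverage.

The final priority order is betweenness descending, closeness
descending as tie-break, then symbol ascending.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import EdgeRecord, normalize_symbol

__all__ = ["TypedGraph", "CentralityScore", "EnrichmentResult", "build_graph",
           "hypergeometric_enrich", "select_seeds", "extract_subnetwork",
           "betweenness", "closeness", "centrality_scores", "prioritize",
           "prioritize_scores"]


@dataclass
class TypedGraph:
    """Vertices + typed undirected edges, with a candidate-marker flag."""

    vertices: set[str]
    edges: set[EdgeRecord]
    marker_flag: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.a not in self.vertices or e.b not in self.vertices:
                raise ValueError(f"edge {e} has endpoint outside vertex set")
        for v in self.vertices:
            self.marker_flag.setdefault(v, False)

    def to_networkx(self) -> nx.Graph:
        """Simple undirected graph with kinds collapsed (for centrality)."""
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from((e.a, e.b) for e in self.edges)
        return g

    @property
    def markers(self) -> set[str]:
        return {v for v, f in self.marker_flag.items() if f}


@dataclass(frozen=True)
class CentralityScore:
    gene: str
    betweenness: float
    closeness_farness: float
    closeness_standard: float


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    candidate_size: int
    universe_size: int
    p_value: float
    q_value: float


def build_graph(markers: set[str], edges: list[EdgeRecord]) -> TypedGraph:
    """Assemble the typed graph; vertices = markers plus edge endpoints."""
    markers = {normalize_symbol(m) for m in markers}
    vertices = set(markers)
    for e in edges:
        vertices.update((e.a, e.b))
    return TypedGraph(
        vertices=vertices,
        edges=set(edges),
        marker_flag={v: v in markers for v in vertices},
    )


def hypergeometric_enrich(
    candidates: set[str], sets: list, universe: set[str]
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation test per gene set.

    Each set is intersected with the universe before testing; p-values are
    upper-tail (P[X >= overlap]) and BH-adjusted across sets. Sorted by p.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    stray = candidates - universe
    if stray:
        raise ValueError(f"candidates outside universe: {sorted(stray)[:5]}")
    results = []
    pvals = []
    for gs in sets:
        members = gs.members & universe
        overlap = len(members & candidates)
        # P[X >= overlap] drawing |candidates| from universe with |members| marked
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(candidates)))
        p = min(max(p, 0.0), 1.0) or 1e-300
        pvals.append(p)
        results.append((gs.name, overlap, len(members)))
    if not results:
        return []
    qvals = multipletests(pvals, method="fdr_bh")[1]
    out = [
        EnrichmentResult(
            set_name=name, overlap=k, set_size=m,
            candidate_size=len(candidates), universe_size=len(universe),
            p_value=p, q_value=float(q),
        )
        for (name, k, m), p, q in zip(results, pvals, qvals)
    ]
    return sorted(out, key=lambda r: (r.p_value, r.set_name))


def select_seeds(
    enrichments: list[EnrichmentResult], sets: list, candidates: set[str],
    target_set: str,
) -> set[str]:
    """Candidates belonging to the named (e.g. growth/proliferation) set."""
    by_name = {gs.name: gs for gs in sets}
    if target_set not in by_name:
        raise KeyError(f"unknown gene set {target_set!r}; available: {sorted(by_name)}")
    return candidates & by_name[target_set].members


def extract_subnetwork(
    graph: TypedGraph, seeds: set[str], include_shared_neighbors: bool = False
) -> TypedGraph:
    """Induced subgraph on the seeds (optionally plus shared neighbors)."""
    seeds = {normalize_symbol(s) for s in seeds}
    missing = seeds - graph.vertices
    if missing:
        warnings.warn(f"seeds not in graph, skipped: {sorted(missing)}", stacklevel=2)
        seeds -= missing
    keep = set(seeds)
    if include_shared_neighbors:
        g = graph.to_networkx()
        for v in graph.vertices - seeds:
            if sum(1 for n in g.neighbors(v) if n in seeds) >= 2:
                keep.add(v)
    return TypedGraph(
        vertices=keep,
        edges={e for e in graph.edges if e.a in keep and e.b in keep},
        marker_flag={v: graph.marker_flag.get(v, False) for v in keep},
    )


def betweenness(graph: TypedGraph) -> dict[str, float]:
    """Unnormalized Freeman betweenness (kinds collapsed, unweighted)."""
    g = graph.to_networkx()
    return {v: float(b) for v, b in nx.betweenness_centrality(g, normalized=False).items()}


def closeness(graph: TypedGraph) -> dict[str, tuple[float, float]]:
    """Per-vertex (farness, standard closeness).

    farness: mean geodesic distance to reachable vertices, 0 if isolated.
    standard: (reachable count)/(distance sum) scaled by component
    coverage (the Wasserman–Faust correction for disconnected graphs).
    """
    g = graph.to_networkx()
    standard = nx.closeness_centrality(g, wf_improved=True)
    out: dict[str, tuple[float, float]] = {}
    for v in g.nodes:
        dists = nx.single_source_shortest_path_length(g, v)
        dists.pop(v, None)
        farness = sum(dists.values()) / len(dists) if dists else 0.0
        out[v] = (float(farness), float(standard[v]))
    return out


def centrality_scores(graph: TypedGraph) -> list[CentralityScore]:
    bc = betweenness(graph)
    cc = closeness(graph)
    return [
        CentralityScore(gene=v, betweenness=bc[v],
                        closeness_farness=cc[v][0], closeness_standard=cc[v][1])
        for v in sorted(graph.vertices)
    ]


def prioritize_scores(
    scores: pd.DataFrame, k: int, closeness_col: str = "closeness"
) -> list[str]:
    """Rank genes from a (gene, betweenness, closeness) score table.

    Order: betweenness descending, closeness descending, symbol ascending.
    """
    if k > len(scores):
        raise ValueError(f"k={k} exceeds {len(scores)} scored vertices")
    ranked = scores.sort_values(
        ["betweenness", closeness_col, "gene"], ascending=[False, False, True]
    )
    return [normalize_symbol(g) for g in ranked["gene"].head(k)]


def prioritize(scores: list[CentralityScore], k: int,
               closeness_attr: str = "closeness_standard") -> list[str]:
    """Top-k genes by betweenness, closeness tie-break, then symbol."""
    df = pd.DataFrame(
        {
            "gene": [s.gene for s in scores],
            "betweenness": [s.betweenness for s in scores],
            "closeness": [getattr(s, closeness_attr) for s in scores],
        }
    )
    return prioritize_scores(df, k)
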