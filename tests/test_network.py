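"""Typed graphs, enrichment, centrality and prioritization."""

import itertools

import numpy as np
import pytest
from scipy import stats

from _oracles import brute_betweenness, brute_farness, brute_hypergeom_p
from urimine.io import EdgeRecord, GeneSet
from urimine.network import (CentralityScore, betweenness, build_graph,
                             centrality_scores, closeness, extract_subnetwork,
                             hypergeometric_enrich, prioritize,
                             prioritize_scores, select_seeds)


def _graph(edges, markers=()):
    return build_graph(set(markers), [EdgeRecord(a, b, k) for a, b, k in edges])


# ---------------------------------------------------------------------------
# graph construction


def test_build_graph_vertices_and_flags():
    g = _graph([("M1", "AUX", "physical")], markers={"M1", "M2"})
    assert g.vertices == {"M1", "M2", "AUX"}
    assert g.marker_flag == {"M1": True, "M2": True, "AUX": False}


def test_build_graph_no_edges_isolated_markers():
    g = _graph([], markers={f"M{i}" for i in range(19)})
    assert len(g.vertices) == 19
    assert all(g.marker_flag.values())
    assert all(b == 0.0 for b in betweenness(g).values())


def test_parallel_edges_need_distinct_kinds():
    g = _graph([("CD70", "CD27", "colocalization"), ("CD70", "CD27", "physical")])
    assert len(g.edges) == 2
    assert g.to_networkx().number_of_edges() == 1  # collapsed for centrality


# ---------------------------------------------------------------------------
# enrichment


def test_hypergeometric_exact_small_case():
    """Universe 10, marked set 5, draw 4, overlap 4: the upper tail is the
    single atom C(5,4)C(5,0)/C(10,4) = 5/210, confirmed by enumeration."""
    universe = {f"G{i}" for i in range(10)}
    members = {f"G{i}" for i in range(5)}
    candidates = {f"G{i}" for i in range(4)}
    (res,) = hypergeometric_enrich(candidates, [GeneSet("S", "", members)], universe)
    assert res.p_value == pytest.approx(
        brute_hypergeom_p(universe, members, candidates))
    assert res.p_value == pytest.approx(5 / 210)


def test_zero_overlap_gives_p_one():
    universe = {f"G{i}" for i in range(10)}
    (res,) = hypergeometric_enrich(
        {"G9"}, [GeneSet("S", "", {"G0", "G1"})], universe)
    assert res.p_value == pytest.approx(1.0)


def test_enrichment_matches_enumeration_on_random_instances():
    rng = np.random.default_rng(8)
    for _ in range(10):
        u = int(rng.integers(8, 16))
        universe = {f"G{i}" for i in range(u)}
        members = set(rng.choice(sorted(universe), size=int(rng.integers(2, u)), replace=False))
        candidates = set(rng.choice(sorted(universe), size=int(rng.integers(2, 7)), replace=False))
        (res,) = hypergeometric_enrich(candidates, [GeneSet("S", "", members)], universe)
        assert res.p_value == pytest.approx(
            brute_hypergeom_p(universe, members, candidates), rel=1e-9)


def test_enrichment_null_distribution_is_exact():
    """Over random candidate draws the p-value ECDF matches the exact
    discrete null CDF (DKW band), and P(p <= 0.05) <= 0.05 + band."""
    rng = np.random.default_rng(21)
    universe = sorted(f"G{i:03d}" for i in range(100))
    members = set(universe[:40])
    gs = GeneSet("S", "", members)
    n_draw, reps = 15, 1000
    pvals = []
    for _ in range(reps):
        cand = set(rng.choice(universe, size=n_draw, replace=False))
        (res,) = hypergeometric_enrich(cand, [gs], set(universe))
        pvals.append(res.p_value)
    # exact null: overlap ~ Hypergeom(100, 40, 15); p = sf(k-1)
    ks = np.arange(0, n_draw + 1)
    pmf = stats.hypergeom.pmf(ks, 100, 40, n_draw)
    atom_p = stats.hypergeom.sf(ks - 1, 100, 40, n_draw)
    pvals = np.asarray(pvals)
    eps = np.sqrt(np.log(2 / 1e-3) / (2 * reps))  # DKW, alpha = 1e-3
    for threshold in np.unique(atom_p):
        exact = pmf[atom_p <= threshold].sum()
        empirical = (pvals <= threshold + 1e-12).mean()
        assert abs(empirical - exact) < eps
    assert (pvals <= 0.05).mean() <= 0.05 + eps


def test_select_seeds_is_candidate_set_intersection():
    sets = [GeneSet("growth", "", {"A", "B", "X"})]
    assert select_seeds([], sets, {"A", "B", "C"}, "growth") == {"A", "B"}
    assert select_seeds([], sets, {"C"}, "growth") == set()
    assert select_seeds([], [GeneSet("g", "", {"A", "B", "C"})], {"A", "B"}, "g") == {"A", "B"}
    with pytest.raises(KeyError, match="growth"):
        select_seeds([], sets, {"A"}, "decay")


# ---------------------------------------------------------------------------
# subnetwork


def test_extract_subnetwork_variants():
    g = _graph([("A", "B", "physical"), ("B", "C", "physical"), ("A", "C", "physical")])
    assert extract_subnetwork(g, {"A", "B", "C"}).edges == g.edges  # identity
    single = extract_subnetwork(g, {"A"})
    assert single.vertices == {"A"} and not single.edges
    pair = extract_subnetwork(g, {"A", "B"})
    assert {(e.a, e.b) for e in pair.edges} == {("A", "B")}


def test_extract_subnetwork_warns_on_missing_seed():
    g = _graph([("A", "B", "physical")])
    with pytest.warns(UserWarning, match="GHOST"):
        sub = extract_subnetwork(g, {"A", "GHOST"})
    assert sub.vertices == {"A"}


# ---------------------------------------------------------------------------
# centrality


def test_path_and_star_closed_forms():
    path = _graph([("A", "B", "physical"), ("B", "C", "physical")])
    bc = betweenness(path)
    assert bc == {"A": 0.0, "B": 1.0, "C": 0.0}
    cc = closeness(path)
    assert cc["B"][0] == pytest.approx(1.0)
    assert cc["A"][0] == pytest.approx(1.5)
    star = _graph([("HUB", f"L{i}", "physical") for i in range(3)])
    assert betweenness(star)["HUB"] == pytest.approx(3.0)  # C(3,2) pairs


def test_isolated_vertex_farness_zero_by_convention():
    g = _graph([("A", "B", "physical")], markers={"LONER"})
    far, standard = closeness(g)["LONER"]
    assert far == 0.0 and standard == 0.0


def _random_typed_graph(rng, n):
    nodes = [f"V{i}" for i in range(n)]
    edges = []
    for a, b in itertools.combinations(nodes, 2):
        if rng.random() < 0.4:
            edges.append((a, b, "physical"))
    return _graph(edges, markers=set(nodes))


def test_centrality_matches_path_enumeration_oracle():
    rng = np.random.default_rng(123)
    for _ in range(40):
        n = int(rng.integers(3, 9))
        g = _random_typed_graph(rng, n)
        pairs = [(e.a, e.b) for e in g.edges]
        bc = betweenness(g)
        oracle_bc = brute_betweenness(g.vertices, pairs)
        for v in g.vertices:
            assert bc[v] == pytest.approx(oracle_bc[v], abs=1e-9)
        far = {v: f for v, (f, _) in closeness(g).items()}
        oracle_far = brute_farness(g.vertices, pairs)
        for v in g.vertices:
            assert far[v] == pytest.approx(oracle_far[v], abs=1e-9)


def test_tree_betweenness_sum_matches_oracle():
    rng = np.random.default_rng(6)
    for _ in range(10):
        n = int(rng.integers(3, 9))
        nodes = [f"V{i}" for i in range(n)]
        edges = [(nodes[i], nodes[int(rng.integers(0, i))], "physical")
                 for i in range(1, n)]
        g = _graph(edges)
        oracle = brute_betweenness(g.vertices, [(e.a, e.b) for e in g.edges])
        assert sum(betweenness(g).values()) == pytest.approx(sum(oracle.values()))
        # degree <= 1 vertices in a tree mediate nothing
        nxg = g.to_networkx()
        for v, deg in nxg.degree:
            if deg <= 1:
                assert betweenness(g)[v] == 0.0


def test_planted_hub_wins_betweenness_rank():
    """A star core plus sparse noise: the hub ranks first by betweenness in
    >= 95% of replicates."""
    rng = np.random.default_rng(99)
    wins, reps = 0, 200
    nodes = [f"V{i}" for i in range(12)]
    for _ in range(reps):
        hub = nodes[int(rng.integers(len(nodes)))]
        edges = [(hub, v, "physical") for v in nodes if v != hub]
        for a, b in itertools.combinations(nodes, 2):
            if hub not in (a, b) and rng.random() < 0.1:
                edges.append((a, b, "coexpression"))
        bc = betweenness(_graph(edges))
        if max(bc, key=lambda v: (bc[v], v)) == hub:
            wins += 1
    assert wins / reps >= 0.95


# ---------------------------------------------------------------------------
# prioritization


def test_published_scores_rank_expected_top3(subnetwork_scores):
    top3 = prioritize_scores(subnetwork_scores, 3)
    assert set(top3) == {"LGALS3", "PECAM1", "MGAT5"}
    assert top3[0] == "LGALS3"


def test_all_zero_scores_tie_break_alphabetical():
    scores = [CentralityScore(g, 0.0, 0.0, 0.0) for g in ["ZZZ", "AAA", "MMM"]]
    assert prioritize(scores, 2) == ["AAA", "MMM"]


def test_full_ranking_is_total_order():
    scores = [CentralityScore(f"G{i}", float(i % 3), 0.0, float(i)) for i in range(7)]
    ranked = prioritize(scores, 7)
    assert len(ranked) == len(set(ranked)) == 7
    with pytest.raises(ValueError):
        prioritize(scores, 8)


def test_centrality_scores_cover_all_vertices():
    g = _graph([("A", "B", "physical")], markers={"C"})
    scores = centrality_scores(g)
    assert {s.gene for s in scores} == {"A", "B", "C"}
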