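"""True-path propagation, term frequencies, and the urinary filter."""

import numpy as np
import pytest

from _oracles import reachable_ancestors
from urimine.io import AnnotationRecord
from urimine.ontology import (ControlledTermSet, OntologyDAG, TermFrequency,
                              filter_by_terms, flag_fluid_presence,
                              propagate_annotations, read_ontology_dag,
                              select_controlled_terms, term_frequencies)

#: The six controlled-vocabulary frequencies the urinary proteome yields.
SIX_TERMS = [
    ("Extracelluar region part", 0.348),
    ("Response to stimulus", 0.255),
    ("Cell adhesion", 0.132),
    ("Calcium ion binding", 0.113),
    ("Cell communication", 0.055),
    ("Amine metabolic process", 0.019),
]


def _chain_dag():
    return OntologyDAG(
        terms={"root", "parent", "child"},
        parents={"parent": {"root"}, "child": {"parent"}},
    )


def test_propagation_reaches_all_ancestors():
    dag = _chain_dag()
    out = propagate_annotations([AnnotationRecord("G1", "child")], dag)
    assert out == {
        AnnotationRecord("G1", "child"),
        AnnotationRecord("G1", "parent"),
        AnnotationRecord("G1", "root"),
    }


def test_propagation_of_root_is_identity():
    dag = _chain_dag()
    records = [AnnotationRecord("G1", "root")]
    assert propagate_annotations(records, dag) == set(records)


def test_propagation_idempotent_monotone_and_matches_reachability():
    rng = np.random.default_rng(12)
    terms = [f"T{i}" for i in range(30)]
    parents = {}
    for i, t in enumerate(terms[1:], start=1):
        # parents only among earlier terms: guarantees acyclicity
        k = rng.integers(1, 3)
        parents[t] = set(rng.choice(terms[:i], size=min(k, i), replace=False))
    dag = OntologyDAG(terms=set(terms), parents=parents)
    annots = [AnnotationRecord(f"G{i}", terms[int(rng.integers(30))]) for i in range(40)]
    once = propagate_annotations(annots, dag)
    assert once >= set(annots)
    assert propagate_annotations(sorted(once, key=lambda r: (r.gene, r.term)), dag) == once
    for rec in annots:
        expected = reachable_ancestors(parents, rec.term) | {rec.term}
        got = {r.term for r in once if r.gene == rec.gene}
        assert expected <= got


def test_propagation_unknown_term_named():
    with pytest.raises(KeyError, match="mystery"):
        propagate_annotations([AnnotationRecord("G1", "mystery")], _chain_dag())


def test_cyclic_relations_rejected():
    with pytest.raises(ValueError, match="cycle"):
        OntologyDAG(terms={"a", "b"}, parents={"a": {"b"}, "b": {"a"}})


def test_term_frequency_direct_count():
    roster = {f"G{i}" for i in range(10)}
    annots = {AnnotationRecord(f"G{i}", "cell adhesion") for i in range(4)}
    annots |= {AnnotationRecord("X1", "cell adhesion")}  # non-roster: ignored
    (freq,) = term_frequencies(roster, annots)
    assert freq.frequency == pytest.approx(0.40)


def test_term_with_no_roster_member_omitted():
    roster = {"G1"}
    annots = {AnnotationRecord("Z9", "elsewhere")}
    assert term_frequencies(roster, annots) == []
    with pytest.raises(ValueError):
        term_frequencies(set(), annots)


def _six_freqs():
    return [TermFrequency(term=t, label=t, frequency=f) for t, f in SIX_TERMS]


def test_controlled_selection_keeps_all_six_at_default_threshold():
    chosen = select_controlled_terms(_six_freqs(), min_frequency=0.019)
    assert [t.term for t in chosen.terms] == [t for t, _ in SIX_TERMS]
    assert chosen.min_frequency == 0.019


def test_controlled_selection_threshold_arithmetic():
    chosen = select_controlled_terms(_six_freqs(), min_frequency=0.20)
    assert {t.term for t in chosen.terms} == {
        "Extracelluar region part", "Response to stimulus"}
    with pytest.warns(UserWarning, match="no term"):
        empty = select_controlled_terms(_six_freqs(), min_frequency=0.50)
    assert empty.terms == []


def test_controlled_selection_explicit_override():
    chosen = select_controlled_terms(
        _six_freqs(), min_frequency=0.50, explicit=["Cell adhesion"])
    assert [t.term for t in chosen.terms] == ["Cell adhesion"]


def test_filter_by_terms_via_descendant_annotation():
    dag = OntologyDAG(
        terms={"cell adhesion", "homophilic adhesion"},
        parents={"homophilic adhesion": {"cell adhesion"}},
    )
    propagated = propagate_annotations(
        [AnnotationRecord("PECAM1", "homophilic adhesion")], dag)
    controlled = ControlledTermSet(
        terms=[TermFrequency("cell adhesion", "cell adhesion", 0.132)])
    assert filter_by_terms({"PECAM1", "NAKED"}, propagated, controlled) == {"PECAM1"}


def test_filter_output_is_subset_and_grows_with_terms():
    annots = {AnnotationRecord("A", "t1"), AnnotationRecord("B", "t2")}
    one = ControlledTermSet(terms=[TermFrequency("t1", "t1", 0.5)])
    two = ControlledTermSet(terms=[TermFrequency("t1", "t1", 0.5),
                                   TermFrequency("t2", "t2", 0.3)])
    candidates = {"A", "B", "C"}
    got_one = filter_by_terms(candidates, annots, one)
    got_two = filter_by_terms(candidates, annots, two)
    assert got_one <= got_two <= candidates
    assert got_one == {"A"} and got_two == {"A", "B"}


def test_dropout_recall_follows_one_minus_d_to_k():
    """With annotation dropout rate d, a gene carrying k controlled terms
    survives the filter with probability 1 - d^k (independent drops)."""
    rng = np.random.default_rng(77)
    d, n_reps = 0.2, 500
    controlled = ControlledTermSet(
        terms=[TermFrequency(f"t{j}", f"t{j}", 0.5) for j in range(2)])
    for k in (1, 2):
        expected = 1 - d ** k
        survived = 0
        for i in range(n_reps):
            annots = {AnnotationRecord("G1", f"t{j}")
                      for j in range(k) if rng.random() > d}
            if filter_by_terms({"G1"}, annots, controlled):
                survived += 1
        rate = survived / n_reps
        tol = 5 * np.sqrt(expected * (1 - expected) / n_reps)
        assert abs(rate - expected) < tol


def test_flag_fluid_presence_against_rosters(marker_fixture):
    urine = {m.gene for m in marker_fixture if m.in_urine}
    blood = {m.gene for m in marker_fixture if m.in_blood}
    flags = flag_fluid_presence({m.gene for m in marker_fixture}, urine, blood)
    assert len(flags) == 19
    assert sum(f.in_urine and f.in_blood for f in flags) == 9
    assert all(f.in_urine for f in flags)
    # empty urine roster: everything flagged absent (dropped downstream)
    none = flag_fluid_presence({"A", "B"}, set(), {"A"})
    assert all(not f.in_urine for f in none)


def test_read_ontology_dag_roundtrip(tmp_path):
    p = tmp_path / "dag.tsv"
    p.write_text("root\t\nparent\troot\nchild\tparent\tChild Label\n")
    dag = read_ontology_dag(p)
    assert dag.ancestors("child") == {"parent", "root"}
    assert dag.label("child") == "Child Label"
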