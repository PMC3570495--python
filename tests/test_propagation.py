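"""Term propagation SOP, BBH computation, and candidate detection."""

import random

import pandas as pd
import pytest

from conftest import make_hits, simple_store
from phenoassert.propagation import (
    CandidateParams,
    PropagationParams,
    compute_bbh,
    detect_candidates,
    propagate_terms,
)
from phenoassert.store import TERM_COLS


def _store_with_terms(term_rows, n_genomes=7, genes_per_genome=3):
    store = simple_store(n_genomes, genes_per_genome)
    store.term_assignments = pd.DataFrame(term_rows, columns=TERM_COLS)
    store.validate()
    return store


def _homolog_hits(query, subjects, identity, coverage, score_base=100.0):
    rows = []
    for i, s in enumerate(subjects):
        rows.append((query, s, identity, coverage, coverage, score_base - i))
    return make_hits(rows)


# subjects in distinct genomes G1..G6 of the simple_store scaffold
SUBJECTS = [f"G{i}_g0" for i in range(1, 7)]


def test_propagation_fires_with_six_qualifying_homologs():
    """Six homologs at 60% identity / 0.8 coverage, three of the top five
    carrying T1: the gene inherits T1 with propagated provenance."""
    store = _store_with_terms([(s, "T1", "manual") for s in SUBJECTS[:3]])
    hits = _homolog_hits("G0_g0", SUBJECTS, identity=60, coverage=0.8)
    out = propagate_terms(store, hits)
    assert out.values.tolist() == [["G0_g0", "T1", "propagated"]]


def test_propagation_needs_min_homologs():
    store = _store_with_terms([(s, "T1", "manual") for s in SUBJECTS[:3]])
    hits = _homolog_hits("G0_g0", SUBJECTS[:4], identity=60, coverage=0.8)
    assert len(propagate_terms(store, hits)) == 0


def test_propagation_needs_min_supporting():
    store = _store_with_terms([(SUBJECTS[0], "T1", "manual")])
    hits = _homolog_hits("G0_g0", SUBJECTS[:5], identity=60, coverage=0.8)
    assert len(propagate_terms(store, hits)) == 0


@pytest.mark.parametrize(
    "identity,coverage,expect",
    [
        (50.0, 0.8, 0),  # identity exactly at threshold: strict > fails
        (50.5, 0.8, 1),
        (60.0, 0.70, 0),  # coverage exactly at threshold fails
        (60.0, 0.705, 1),
    ],
)
def test_propagation_thresholds_are_strict(identity, coverage, expect):
    store = _store_with_terms([(s, "T1", "manual") for s in SUBJECTS[:2]])
    hits = _homolog_hits("G0_g0", SUBJECTS[:5], identity=identity, coverage=coverage)
    assert len(propagate_terms(store, hits)) == expect


def test_support_counted_among_top_five_only():
    """A term carried only by homologs ranked below the top five never
    propagates, even if its total support is sufficient."""
    store = _store_with_terms(
        [(s, "T_low", "manual") for s in SUBJECTS[4:6]]
        + [(s, "T_top", "manual") for s in SUBJECTS[:2]]
    )
    rows = []
    for i, s in enumerate(SUBJECTS):  # identities descending with index
        rows.append(("G0_g0", s, 90 - i * 5, 0.8, 0.8, 100))
    out = propagate_terms(store, make_hits(rows))
    assert out["term_id"].tolist() == ["T_top"]


def test_propagation_skips_genes_with_confirmed_terms_and_is_idempotent():
    store = _store_with_terms(
        [(s, "T1", "manual") for s in SUBJECTS[:3]] + [("G0_g0", "T9", "manual")]
    )
    hits = _homolog_hits("G0_g0", SUBJECTS, identity=60, coverage=0.8)
    assert len(propagate_terms(store, hits)) == 0
    # candidate provenance does not block propagation
    store2 = _store_with_terms(
        [(s, "T1", "manual") for s in SUBJECTS[:3]] + [("G0_g0", "T1", "candidate")]
    )
    out = propagate_terms(store2, hits)
    assert out["term_id"].tolist() == ["T1"]
    # same inputs, same output
    assert out.equals(propagate_terms(store2, hits))


def test_propagation_order_invariance():
    store = _store_with_terms([(s, "T1", "manual") for s in SUBJECTS[:3]])
    rows = [("G0_g0", s, 60, 0.8, 0.8, 100 - i) for i, s in enumerate(SUBJECTS)]
    shuffled = rows[::-1]
    a = propagate_terms(store, make_hits(rows))
    b = propagate_terms(store, make_hits(shuffled))
    assert a.equals(b)


def test_propagation_iterates_to_fixpoint():
    """With --iterate, a gene whose homologs gain terms in round one can be
    assigned in round two."""
    store = _store_with_terms([(s, "T1", "manual") for s in SUBJECTS[:2]])
    # G0_g0 qualifies off SUBJECTS; G0_g1 sees only one manual carrier, so it
    # reaches two supporters only after G0_g0 inherits the term
    rows = [("G0_g0", s, 60, 0.8, 0.8, 100) for s in SUBJECTS[:5]]
    rows += [("G0_g1", s, 55, 0.8, 0.8, 90) for s in ["G0_g0"] + SUBJECTS[1:5]]
    one_round = propagate_terms(store, make_hits(rows))
    assert one_round["gene_id"].tolist() == ["G0_g0"]
    fixpoint = propagate_terms(store, make_hits(rows), iterate=True)
    assert fixpoint["gene_id"].tolist() == ["G0_g0", "G0_g1"]


# ---------------------------------------------------------------------------
# BBH


def test_bbh_symmetric_pair():
    hits = make_hits([("a", "b", 80, 0.9, 0.9, 100), ("b", "a", 80, 0.9, 0.9, 100)])
    genome_of = {"a": "G1", "b": "G2"}
    assert compute_bbh(hits, genome_of) == {frozenset({"a", "b"})}


def test_bbh_requires_mutuality():
    """a's best in G2 is b, but b's best in G1 is c: no (a, b) pair."""
    hits = make_hits(
        [
            ("a", "b", 80, 0.9, 0.9, 100),
            ("b", "a", 80, 0.9, 0.9, 90),
            ("b", "c", 85, 0.9, 0.9, 95),
            ("c", "b", 85, 0.9, 0.9, 95),
        ]
    )
    genome_of = {"a": "G1", "c": "G1", "b": "G2"}
    assert compute_bbh(hits, genome_of) == {frozenset({"b", "c"})}


def test_bbh_never_within_one_genome():
    hits = make_hits([("a", "b", 80, 0.9, 0.9, 100), ("b", "a", 80, 0.9, 0.9, 100)])
    assert compute_bbh(hits, {"a": "G1", "b": "G1"}) == set()


def test_bbh_best_ties_broken_by_identity_then_id():
    hits = make_hits(
        [
            ("a", "b1", 70, 0.9, 0.9, 100),
            ("a", "b2", 80, 0.9, 0.9, 100),  # same score, higher identity wins
            ("b2", "a", 80, 0.9, 0.9, 100),
            ("b1", "a", 70, 0.9, 0.9, 100),
        ]
    )
    genome_of = {"a": "G1", "b1": "G2", "b2": "G2"}
    assert compute_bbh(hits, genome_of) == {frozenset({"a", "b2"})}


# ---------------------------------------------------------------------------
# Candidate detection


def _candidate_setup(bearer_idents, coverage=0.75):
    """Gene G0_g0 with BBH partners in distinct genomes; the first
    len(bearer_idents) partners carry T and have the given identities."""
    n = len(bearer_idents)
    store = _store_with_terms([(f"G{i+1}_g0", "T", "manual") for i in range(n)])
    rows = []
    for i, ident in enumerate(bearer_idents):
        partner = f"G{i+1}_g0"
        rows.append(("G0_g0", partner, ident, coverage, coverage, ident * 10))
        rows.append((partner, "G0_g0", ident, coverage, coverage, ident * 10))
    return store, make_hits(rows)


def test_candidate_detected_when_one_bearer_exceeds_best_identity():
    store, hits = _candidate_setup([30.0, 20.0])
    out = detect_candidates(store, hits)
    assert out.values.tolist() == [["G0_g0", "T", "candidate"]]


def test_candidate_requires_best_identity_above_25():
    store, hits = _candidate_setup([24.0, 20.0])
    assert len(detect_candidates(store, hits)) == 0
    # exactly 25 also fails (strict inequality)
    store, hits = _candidate_setup([25.0, 20.0])
    assert len(detect_candidates(store, hits)) == 0


def test_candidate_requires_two_supporting_partners():
    store, hits = _candidate_setup([30.0])
    assert len(detect_candidates(store, hits)) == 0


def test_candidate_requires_coverage_above_070():
    store, hits = _candidate_setup([30.0, 28.0], coverage=0.70)
    assert len(detect_candidates(store, hits)) == 0


def test_candidate_never_duplicates_confirmed_assignment():
    store, hits = _candidate_setup([30.0, 28.0])
    store.add_term_assignments(
        pd.DataFrame([("G0_g0", "T", "manual")], columns=TERM_COLS)
    )
    assert len(detect_candidates(store, hits)) == 0


def test_candidate_support_counted_within_top_k():
    """Bearers pushed below the top-5 by higher-identity non-bearers do not
    count as support."""
    store = _store_with_terms(
        [(f"G{i+1}_g0", "T", "manual") for i in range(2)]  # bearers in G1, G2
    )
    rows = []
    # five non-bearer partners at high identity occupy the top 5
    for i in range(5):
        partner = f"G{i+3}_g0" if i < 4 else "G2_g1"
        rows.append(("G0_g0", partner, 60 - i, 0.8, 0.8, 100))
        rows.append((partner, "G0_g0", 60 - i, 0.8, 0.8, 100))
    for i in range(2):  # bearers at low identity
        partner = f"G{i+1}_g0"
        rows.append(("G0_g0", partner, 30 - i, 0.8, 0.8, 50))
        rows.append((partner, "G0_g0", 30 - i, 0.8, 0.8, 50))
    out = detect_candidates(store, make_hits(rows))
    assert len(out) == 0


def test_candidate_and_propagated_disjoint_random():
    """On random hit tables, no (gene, term) pair appears both propagated
    and candidate once propagation output is committed first."""
    rng = random.Random(5)
    store = simple_store(4, 5)
    term_rows = [
        (f"G{g}_g{j}", f"T{rng.randrange(3)}", "manual")
        for g in range(4)
        for j in range(2)
    ]
    store.term_assignments = pd.DataFrame(term_rows, columns=TERM_COLS).drop_duplicates(
        ignore_index=True
    )
    store.validate()
    rows = []
    genes = [f"G{g}_g{j}" for g in range(4) for j in range(5)]
    for q in genes:
        for s in rng.sample(genes, 6):
            if q == s:
                continue
            ident = rng.uniform(10, 95)
            rows.append((q, s, ident, rng.uniform(0.5, 1.0), rng.uniform(0.5, 1.0), ident))
    hits = make_hits(rows)
    store.add_term_assignments(propagate_terms(store, hits))
    store.add_term_assignments(detect_candidates(store, hits))
    ta = store.term_assignments
    pairs = ta.groupby(["gene_id", "term_id"])["provenance"].apply(set)
    assert not any({"candidate"} < s for s in pairs)
    store.validate()  # enforces candidate/confirmed disjointness
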