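"""Fingerprint similarity: formulas vs brute-force oracles, laws, top-k."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from zbscreen.chem import MoleculeRecord, records_from_smiles
from zbscreen.fingerprints import (
    MEASURES,
    SCHEMES,
    SimilarityComponents,
    components,
    fingerprint,
    run_similarity_battery,
    similarity,
    top_k,
)
from zbscreen.synth import synth_library


def fp_from_entries(entries, scheme="atom-type"):
    from zbscreen.fingerprints import SparseFingerprint
    return SparseFingerprint(entries=entries, scheme=scheme)


# --- fingerprint construction -------------------------------------------------

def test_fingerprint_deterministic_and_nonempty():
    rec = records_from_smiles([("C", "methane")])[0]
    a = fingerprint(rec, scheme="atom-type")
    b = fingerprint(rec, scheme="atom-type")
    assert a.entries and a.entries == b.entries


def test_fingerprint_invariant_under_atom_reordering():
    # same graph, different atom order in the input spelling
    a, b = records_from_smiles([("c1ccccc1CCO", "a"), ("OCCc1ccccc1", "b")])
    for scheme in SCHEMES:
        assert fingerprint(a, scheme).entries == fingerprint(b, scheme).entries


def test_related_molecules_share_and_differ():
    eth, prop = records_from_smiles([("CCO", "eth"), ("CCCO", "prop")])
    c = components(fingerprint(eth), fingerprint(prop), mode="bit")
    assert c.SA > 0 and c.SB > 0 and c.SC > 0


def test_scheme_mismatch_rejected():
    rec = records_from_smiles([("CCO", "x")])[0]
    with pytest.raises(ValueError, match="mismatch"):
        components(fingerprint(rec, "atom-type"), fingerprint(rec, "functional-class"))


# --- components: set/count semantics ------------------------------------------

def test_components_bit_mode_set_oracle():
    t = fp_from_entries({1: 1, 2: 1, 3: 1})
    r = fp_from_entries({2: 1, 3: 1, 4: 1})
    c = components(t, r, mode="bit")
    assert (c.SA, c.SB, c.SC) == (2, 1, 1)


def test_components_count_mode_min_arithmetic():
    t = fp_from_entries({7: 3})
    r = fp_from_entries({7: 1})
    c = components(t, r, mode="count")
    assert (c.SA, c.SB, c.SC) == (1, 2, 0)


def test_identical_fingerprints_have_no_difference_bits():
    t = fp_from_entries({1: 2, 5: 1})
    c = components(t, t, mode="bit")
    assert (c.SB, c.SC) == (0, 0)


# --- similarity measures -------------------------------------------------------

def test_printed_formula_values():
    c = SimilarityComponents(SA=2, SB=1, SC=1)
    assert similarity(c, "tanimoto") == pytest.approx(0.5)
    assert similarity(c, "dice") == pytest.approx(2 / 3, abs=1e-4)
    assert similarity(c, "cosine") == pytest.approx(2 / 3, abs=1e-4)


def test_identical_and_disjoint_extremes():
    ident = SimilarityComponents(SA=5, SB=0, SC=0)
    disjoint = SimilarityComponents(SA=0, SB=3, SC=4)
    for m in MEASURES:
        assert similarity(ident, m) == 1.0
        assert similarity(disjoint, m) == 0.0


def test_empty_vs_empty_convention_is_zero():
    for m in MEASURES:
        assert similarity(SimilarityComponents(SA=0, SB=0, SC=0), m) == 0.0


def test_negative_components_rejected():
    with pytest.raises(ValueError):
        SimilarityComponents(SA=-1, SB=0, SC=0)


@settings(deadline=None, max_examples=200)
@given(sa=st.integers(0, 100), sb=st.integers(0, 100), sc=st.integers(0, 100))
def test_similarity_laws_on_randomized_components(sa, sb, sc):
    """Range, symmetry and analytic ordering (dice >= tanimoto, cosine >=
    tanimoto by the AM-GM inequality) for all measures."""
    if sa == sb == sc == 0:
        return
    fwd = SimilarityComponents(SA=sa, SB=sb, SC=sc)
    rev = SimilarityComponents(SA=sa, SB=sc, SC=sb)
    vals = {}
    for m in MEASURES:
        v = similarity(fwd, m)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(similarity(rev, m))
        vals[m] = v
    if sa > 0:
        t = vals["tanimoto"]
        assert vals["dice"] >= t - 1e-12
        assert vals["dice"] == pytest.approx(2 * t / (1 + t))
        assert vals["cosine"] >= t - 1e-12


def test_symmetry_on_real_fingerprints():
    a, b = records_from_smiles([("CCO", "a"), ("CCCNC(C)=O", "b")])
    for scheme, mode in itertools.product(SCHEMES, ("bit", "count")):
        fa, fb = fingerprint(a, scheme), fingerprint(b, scheme)
        for m in MEASURES:
            assert similarity(components(fa, fb, mode), m) == pytest.approx(
                similarity(components(fb, fa, mode), m))


# --- top-k ---------------------------------------------------------------------

def brute_force_top_k(reference, db, k, measure, scheme):
    ref_fp = fingerprint(reference, scheme)
    scored = [(similarity(components(fingerprint(rec, scheme), ref_fp), measure), i, rec.id)
              for i, rec in enumerate(db)]
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [(rid, s) for s, _i, rid in scored[:k]]


def test_top_k_truncates_to_database_size(simple_records):
    hl = top_k(simple_records[0], simple_records, k=500)
    assert len(hl.rows) == len(simple_records)
    assert list(hl.rows["rank"]) == list(range(1, len(simple_records) + 1))


def test_reference_in_database_ranks_first(simple_records):
    hl = top_k(simple_records[0], simple_records, k=3)
    assert hl.rows.iloc[0]["target_id"] == simple_records[0].id
    assert hl.rows.iloc[0]["similarity"] == pytest.approx(1.0)


@pytest.mark.parametrize("measure", MEASURES)
@pytest.mark.parametrize("scheme", SCHEMES)
def test_top_k_equals_exhaustive_scan(measure, scheme):
    db = synth_library(200, seed=3)
    refs = synth_library(2, seed=99, zbg_fraction=1.0, violation_fraction=0.0)
    hl = top_k(refs[0], db, k=10, measure=measure, scheme=scheme)
    oracle = brute_force_top_k(refs[0], db, 10, measure, scheme)
    got = list(zip(hl.rows["target_id"], hl.rows["similarity"]))
    assert [g[0] for g in got] == [o[0] for o in oracle]
    for g, o in zip(got, oracle):
        assert g[1] == pytest.approx(o[1])


def test_similarity_non_increasing_with_rank():
    db = synth_library(100, seed=4)
    hl = top_k(db[0], db, k=50)
    sims = list(hl.rows["similarity"])
    assert all(a >= b for a, b in zip(sims, sims[1:]))


# --- battery -------------------------------------------------------------------

def test_battery_row_arithmetic():
    db = synth_library(100, seed=5)
    refs = db[:2]
    hl = run_similarity_battery(refs, db, k=10, measures=list(MEASURES),
                                schemes=list(SCHEMES))
    assert len(hl.rows) == 2 * 3 * 2 * 10
    assert set(hl.rows["run_id"].unique()) == {
        f"{r.id}|{m}|{s}" for r in refs for m in MEASURES for s in SCHEMES}


def test_battery_small_db_returns_whole_db():
    db = synth_library(7, seed=6)
    hl = run_similarity_battery(db[:1], db, k=500, measures=["tanimoto"],
                                schemes=["atom-type"])
    assert len(hl.rows) == 7
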