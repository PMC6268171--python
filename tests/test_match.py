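"""Pharmacophore matcher: exhaustive oracle equivalence and invariants.

The oracle enumerates every feature subset and injective kind-compatible
point assignment with itertools, and computes the optimal superposition
with scipy's Rotation.align_vectors — an implementation-independent route
to the same optimum the backtracking matcher must find.
"""

import itertools
import math
import random

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from zbscreen.pharmacophore import (
    LigandFeaturePoint,
    PharmacophoreFeature,
    PharmacophoreModel,
    glo1_model,
    match,
    perceive_ligand_features,
    verify_match,
)
from zbscreen.synth import toy_conformer


def oracle_match(points, model):
    """Brute-force best (fit, mapped count) over all acceptable assignments."""
    mandatory = set(model.mandatory_ids)
    need = max(model.min_required, 3)
    best = None
    for size in range(need, len(model.features) + 1):
        for fsub in itertools.combinations(model.features, size):
            fids = {f.id for f in fsub}
            if not mandatory <= fids:
                continue
            options = [[i for i, p in enumerate(points) if p.kind == f.kind]
                       for f in fsub]
            for combo in itertools.product(*options):
                if len(set(combo)) != size:
                    continue
                P = np.array([points[i].position for i in combo])
                Q = np.array([f.center for f in fsub])
                rot, _rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
                moved = rot.apply(P - P.mean(0)) + Q.mean(0)
                tols = np.array([f.tolerance for f in fsub])
                d = np.linalg.norm(moved - Q, axis=1)
                if np.any(d > tols):
                    continue
                fit = float(np.sum(1.0 - d / tols))
                if best is None or (fit, size) > (best[0], best[1]):
                    best = (fit, size)
    return best


def random_case(rng):
    """A small random model (<= 5 features) and <= 6 ligand points."""
    kinds = ["HBD", "HBA", "HY", "NI", "ZB", "RA", "PI"]
    n_feat = rng.randint(3, 5)
    feats = []
    chosen_kinds = [rng.choice(kinds) for _ in range(n_feat)]
    if chosen_kinds.count("ZB") > 1:  # at most one ZB per model
        chosen_kinds = [k if k != "ZB" else "HBA" for k in chosen_kinds[:-1]] + ["ZB"]
    for i, kind in enumerate(chosen_kinds):
        feats.append(PharmacophoreFeature(
            id=f"F{i}", kind=kind,
            center=[rng.uniform(-5, 5) for _ in range(3)],
            tolerance=rng.uniform(1.0, 2.2)))
    model = PharmacophoreModel(features=feats, min_required=3,
                               mandatory_ids=[feats[0].id] if rng.random() < 0.5 else [])
    points = []
    for _ in range(rng.randint(3, 6)):
        if rng.random() < 0.7:  # near a feature of the same kind
            f = rng.choice(feats)
            pos = f.center + np.array([rng.gauss(0, 0.8) for _ in range(3)])
            kind = f.kind
        else:
            pos = np.array([rng.uniform(-6, 6) for _ in range(3)])
            kind = rng.choice(kinds)
        points.append(LigandFeaturePoint(kind=kind, position=pos, atoms=(0,)))
    # random rigid motion so the identity frame is never trivially optimal
    rot = Rotation.from_euler("xyz", [rng.uniform(0, 360) for _ in range(3)], degrees=True)
    shift = np.array([rng.uniform(-4, 4) for _ in range(3)])
    for p in points:
        p.position = rot.apply(p.position) + shift
    return model, points


def test_matcher_equals_exhaustive_oracle_on_small_toys():
    rng = random.Random(20240917)
    n_checked = 0
    for _ in range(40):
        model, points = random_case(rng)
        got = match(points, model)
        want = oracle_match(points, model)
        if want is None:
            assert got is None
        else:
            assert got is not None
            assert got.fit == pytest.approx(want[0], abs=1e-3)
            assert got.mapped_count == want[1]
            n_checked += 1
    assert n_checked >= 5  # the generator must exercise accepting cases


def test_perfect_placement_gives_exact_fit(model):
    # ligand points exactly at 5 feature centers, incl. ZB and adjacent HY
    chosen = ["ZB1", "HY1", "HY2", "HBD1", "HBA1"]
    points = [LigandFeaturePoint(kind=model.feature(fid).kind,
                                 position=model.feature(fid).center, atoms=(0,))
              for fid in chosen]
    res = match(points, model)
    assert res is not None
    assert res.fit == pytest.approx(5.0, abs=1e-9)
    assert res.mapped_count == 5
    assert verify_match(res, points, model)


def test_three_features_is_below_the_minimum(model):
    rec, chosen = toy_conformer(model, k=3, jitter=0.0, seed=2)
    assert set(model.mandatory_ids) <= set(chosen)
    points = perceive_ligand_features(rec)
    assert match(points, model) is None


@pytest.mark.parametrize("k", [4, 5, 7])
def test_toy_conformer_matches_intended_feature_count(model, k):
    rec, chosen = toy_conformer(model, k=k, jitter=0.0, seed=3)
    points = perceive_ligand_features(rec)
    res = match(points, model)
    assert res is not None
    assert res.mapped_count == k
    assert res.fit == pytest.approx(float(k), abs=1e-6)
    assert set(model.mandatory_ids) <= set(res.assignment)
    assert verify_match(res, points, model)


def test_jittered_toy_fit_lower_bound(model):
    """With every point displaced by exactly j, the least-squares transform
    keeps sum(d^2) <= k*j^2, so fit >= k - sqrt(k * k j^2) / min tolerance."""
    k, j = 5, 0.5
    rec, _ = toy_conformer(model, k=k, jitter=j, seed=5)
    points = perceive_ligand_features(rec)
    res = match(points, model)
    assert res is not None and res.mapped_count >= k - 1
    min_tol = min(f.tolerance for f in model.features)
    bound = k - math.sqrt(k * k * j * j) / min_tol
    assert res.fit >= bound - 1e-6


def test_fit_bounds_and_mandatory_enforcement(model):
    for seed in range(4):
        rec, _ = toy_conformer(model, k=5, jitter=0.8, seed=seed)
        points = perceive_ligand_features(rec)
        res = match(points, model)
        if res is None:
            continue
        assert 0.0 <= res.fit <= res.mapped_count <= len(model.features)
        assert set(model.mandatory_ids) <= set(res.assignment)
        for fid, d in res.displacements.items():
            assert d <= model.feature(fid).tolerance + 1e-9
        assert verify_match(res, points, model)


def test_best_fit_invariant_under_rigid_motion(model):
    rec, _ = toy_conformer(model, k=5, jitter=0.4, seed=9)
    points = perceive_ligand_features(rec)
    base = match(points, model)
    rot = Rotation.from_euler("zyx", [31.0, -57.0, 112.0], degrees=True)
    shift = np.array([3.0, -8.0, 2.5])
    moved = [LigandFeaturePoint(kind=p.kind, position=rot.apply(p.position) + shift,
                                atoms=p.atoms) for p in points]
    res = match(moved, model)
    assert (base is None) == (res is None)
    if base is not None:
        assert res.fit == pytest.approx(base.fit, abs=1e-6)
        assert res.mapped_count == base.mapped_count


def test_transform_maps_points_onto_features(model):
    rec, _ = toy_conformer(model, k=6, jitter=0.3, seed=12)
    points = perceive_ligand_features(rec)
    res = match(points, model)
    assert res is not None
    for fid, pidx in res.assignment.items():
        moved = res.rotation @ points[pidx].position + res.translation
        d = float(np.linalg.norm(moved - model.feature(fid).center))
        assert d == pytest.approx(res.displacements[fid], abs=1e-9)
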