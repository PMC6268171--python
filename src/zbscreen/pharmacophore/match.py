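"""Partial pharmacophore matching with rigid superposition and fit scoring.

A match is an injective assignment of kind-compatible ligand feature points
to model features (ZB features accept only ZB points) that

* includes every mandatory feature,
* maps at least ``min_required`` features (and never fewer than three, the
  minimum for a determined rigid transform),
* admits a least-squares rigid superposition (Kabsch) of the mapped ligand
  points onto the feature centers under which every displacement is within
  its feature's tolerance.

Among acceptable assignments the one maximizing

    fit = sum over mapped features of (1 - displacement / tolerance)

is returned; ties are broken by larger mapped count, then by lexicographic
assignment.  fit lies in [0, mapped count] and equals the mapped count only
for zero displacements.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import PharmacophoreFeature, PharmacophoreModel
from .perceive import LigandFeaturePoint

MIN_POINTS_FOR_TRANSFORM = 3

__all__ = ["MatchResult", "kabsch", "match", "verify_match"]


@dataclass
class MatchResult:
    """An accepted feature-to-point assignment with its rigid transform."""

    conformer_id: int
    assignment: dict[str, int]           # feature id -> ligand point index
    displacements: dict[str, float]      # feature id -> Angstrom
    fit: float
    rotation: np.ndarray                 # 3x3, applied to ligand coordinates
    translation: np.ndarray              # 3-vector
    provenance: dict = field(default_factory=dict)

    @property
    def mapped_count(self) -> int:
        return len(self.assignment)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the stored rigid transform to an (n, 3) coordinate array."""
        return coords @ self.rotation.T + self.translation


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping points P onto Q.

    Minimizes sum ||R p_i + t - q_i||^2; proper rotation (det R = +1).
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def _compatible(feature: PharmacophoreFeature, point: LigandFeaturePoint) -> bool:
    return feature.kind == point.kind


def _evaluate(features: Sequence[PharmacophoreFeature],
              points: Sequence[LigandFeaturePoint],
              assignment: dict[str, int]) -> Optional[tuple[float, dict, np.ndarray, np.ndarray]]:
    fids = sorted(assignment)
    P = np.array([points[assignment[f]].position for f in fids])
    centers = {f.id: f for f in features}
    Q = np.array([centers[f].center for f in fids])
    R, t = kabsch(P, Q)
    moved = P @ R.T + t
    disps = {}
    fit = 0.0
    for row, fid in enumerate(fids):
        d = float(np.linalg.norm(moved[row] - centers[fid].center))
        if d > centers[fid].tolerance:
            return None
        disps[fid] = d
        fit += 1.0 - d / centers[fid].tolerance
    return fit, disps, R, t


def match(points: Sequence[LigandFeaturePoint], model: PharmacophoreModel,
          conformer_id: int = 0) -> Optional[MatchResult]:
    """Best acceptable assignment of ligand points to model features, or None.

    All candidate assignments of size >= max(min_required, 3) containing the
    mandatory features are searched; each is scored under its own
    least-squares superposition.
    """
    features = model.features
    mandatory = set(model.mandatory_ids)
    need = max(model.min_required, MIN_POINTS_FOR_TRANSFORM)
    by_kind: dict[str, list[int]] = {}
    for i, p in enumerate(points):
        by_kind.setdefault(p.kind, []).append(i)

    # candidate point lists per feature; bail early if a mandatory feature
    # has no compatible point
    candidates: dict[str, list[int]] = {}
    for f in features:
        candidates[f.id] = by_kind.get(f.kind, [])
        if f.id in mandatory and not candidates[f.id]:
            return None

    order = sorted(features, key=lambda f: (f.id not in mandatory, len(candidates[f.id]), f.id))

    best: Optional[tuple[tuple, MatchResult]] = None

    def consider(assignment: dict[str, int]):
        nonlocal best
        res = _evaluate(features, points, assignment)
        if res is None:
            return
        fit, disps, R, t = res
        lex = tuple(sorted(assignment.items()))
        key = (-fit, -len(assignment), lex)
        if best is None or key < best[0]:
            best = (key, MatchResult(conformer_id=conformer_id, assignment=dict(assignment),
                                     displacements=disps, fit=fit, rotation=R, translation=t))

    n = len(order)

    def recurse(idx: int, used: set[int], assignment: dict[str, int]):
        remaining = n - idx
        if len(assignment) + remaining < need:
            return
        if idx == n:
            if len(assignment) >= need and mandatory <= assignment.keys():
                consider(assignment)
            return
        f = order[idx]
        for p in candidates[f.id]:
            if p in used:
                continue
            assignment[f.id] = p
            used.add(p)
            recurse(idx + 1, used, assignment)
            used.discard(p)
            del assignment[f.id]
        if f.id not in mandatory:
            recurse(idx + 1, used, assignment)

    recurse(0, set(), {})
    return best[1] if best else None


def verify_match(result: MatchResult, points: Sequence[LigandFeaturePoint],
                 model: PharmacophoreModel, atol: float = 1e-9) -> bool:
    """Independently re-check a MatchResult's invariants.

    Re-applies the stored transform, recomputes displacements and fit, and
    confirms tolerance bounds, mandatory coverage and the minimum count.
    """
    if not set(model.mandatory_ids) <= result.assignment.keys():
        return False
    if result.mapped_count < model.min_required:
        return False
    fit = 0.0
    for fid, pidx in result.assignment.items():
        f = model.feature(fid)
        p = points[pidx]
        if not _compatible(f, p):
            return False
        moved = result.rotation @ p.position + result.translation
        d = float(np.linalg.norm(moved - f.center))
        if d > f.tolerance + atol:
            return False
        if abs(d - result.displacements[fid]) > 1e-6:
            return False
        fit += 1.0 - d / f.tolerance
    return abs(fit - result.fit) <= max(atol, 1e-9 * max(1.0, abs(fit)))
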