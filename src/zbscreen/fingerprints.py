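"""Circular fingerprints and 2D similarity search.

Two extended-connectivity schemes are provided, grown to a maximum
topological *diameter* (default 6, i.e. radius 3):

* ``functional-class`` — atoms are seeded with pharmacophoric role flags
  (donor, acceptor, aromatic, ionizable, halogen); the FCFP-style
  abstraction.  Default comparison mode is ``bit`` (duplicates removed).
* ``atom-type`` — atoms are seeded with element, charge, hybridization and
  connectivity; the ECFC-style abstraction.  Default comparison mode is
  ``count`` (duplicates retained).

Similarity between a target and a reference fingerprint is computed from
three overlap components:

* SA — features present in both target and reference,
* SB — features in the target only,
* SC — features in the reference only,

with Tanimoto = SA/(SA+SB+SC), Dice = 2*SA/(2*SA+SB+SC) and
Cosine = SA/sqrt((SA+SB)*(SA+SC)).  In count mode SA is the summed
per-feature minimum count and SB/SC the remainders.

Environment hashing uses RDKit's Morgan generator (fixed 32/64-bit hashing,
versioned with the RDKit release); hash collisions are tolerated.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem import MoleculeRecord

logger = logging.getLogger(__name__)

Scheme = Literal["functional-class", "atom-type"]
Mode = Literal["bit", "count"]
Measure = Literal["tanimoto", "dice", "cosine"]

MEASURES: tuple[Measure, ...] = ("tanimoto", "dice", "cosine")
SCHEMES: tuple[Scheme, ...] = ("functional-class", "atom-type")

#: Default comparison mode per scheme: functional-class removes duplicates,
#: atom-type retains counts.
DEFAULT_MODE: dict[str, Mode] = {"functional-class": "bit", "atom-type": "count"}

__all__ = [
    "SparseFingerprint",
    "SimilarityComponents",
    "HitList",
    "fingerprint",
    "components",
    "similarity",
    "top_k",
    "run_similarity_battery",
    "MEASURES",
    "SCHEMES",
    "DEFAULT_MODE",
]


@dataclass(frozen=True)
class SparseFingerprint:
    """Sparse mapping of hashed circular environments to occurrence counts."""

    entries: dict[int, int]
    scheme: Scheme
    max_distance: int = 6

    def __post_init__(self):
        if any(c < 1 for c in self.entries.values()):
            raise ValueError("fingerprint counts must be >= 1")

    @property
    def n_features(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class SimilarityComponents:
    """Overlap components between a target and a reference fingerprint."""

    SA: float
    SB: float
    SC: float
    mode: Mode = "bit"

    def __post_init__(self):
        if self.SA < 0 or self.SB < 0 or self.SC < 0:
            raise ValueError("similarity components must be non-negative")


@dataclass
class HitList:
    """Ranked similarity-search results with run provenance.

    ``rows`` is a DataFrame with columns reference_id, target_id, measure,
    scheme, similarity, rank, run_id.  Within one run similarity is
    non-increasing with rank.
    """

    rows: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    COLUMNS = ["reference_id", "target_id", "measure", "scheme", "similarity", "rank", "run_id"]

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    @classmethod
    def empty(cls, provenance: Optional[dict] = None) -> "HitList":
        return cls(rows=pd.DataFrame(columns=cls.COLUMNS), provenance=provenance or {})


_GENERATORS: dict[tuple[str, int], object] = {}


def _generator(scheme: Scheme, max_distance: int):
    key = (scheme, max_distance)
    if key not in _GENERATORS:
        radius = max_distance // 2
        if scheme == "functional-class":
            inv = rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
            gen = rdFingerprintGenerator.GetMorganGenerator(
                radius=radius, atomInvariantsGenerator=inv
            )
        elif scheme == "atom-type":
            gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
        else:
            raise ValueError(f"unknown fingerprint scheme: {scheme}")
        _GENERATORS[key] = gen
    return _GENERATORS[key]


def fingerprint(mol: MoleculeRecord | Chem.Mol, scheme: Scheme = "atom-type",
                max_distance: int = 6) -> SparseFingerprint:
    """Compute the sparse circular fingerprint of one molecule.

    An empty molecule yields an empty fingerprint (logged, not fatal).
    """
    rdmol = mol.mol if isinstance(mol, MoleculeRecord) else mol
    if rdmol.GetNumAtoms() == 0:
        logger.warning("empty molecule: empty fingerprint")
        return SparseFingerprint(entries={}, scheme=scheme, max_distance=max_distance)
    gen = _generator(scheme, max_distance)
    fp = gen.GetSparseCountFingerprint(rdmol)
    return SparseFingerprint(
        entries=dict(fp.GetNonzeroElements()), scheme=scheme, max_distance=max_distance
    )


def components(target: SparseFingerprint, reference: SparseFingerprint,
               mode: Optional[Mode] = None) -> SimilarityComponents:
    """Overlap components SA/SB/SC between two fingerprints.

    ``bit`` mode uses set semantics (counts ignored); ``count`` mode uses
    SA = sum of per-feature minimum counts.  When mode is None the scheme
    default applies (bit for functional-class, count for atom-type).
    """
    if target.scheme != reference.scheme or target.max_distance != reference.max_distance:
        raise ValueError(
            "fingerprint scheme mismatch: "
            f"target ({target.scheme}, {target.max_distance}) vs "
            f"reference ({reference.scheme}, {reference.max_distance})"
        )
    if mode is None:
        mode = DEFAULT_MODE[target.scheme]
    t, r = target.entries, reference.entries
    if mode == "bit":
        tk, rk = set(t), set(r)
        sa = len(tk & rk)
        sb = len(tk) - sa
        sc = len(rk) - sa
    elif mode == "count":
        shared = t.keys() & r.keys()
        sa = sum(min(t[k], r[k]) for k in shared)
        sb = sum(t.values()) - sa
        sc = sum(r.values()) - sa
    else:
        raise ValueError(f"unknown mode: {mode}")
    return SimilarityComponents(SA=sa, SB=sb, SC=sc, mode=mode)


def similarity(c: SimilarityComponents, measure: Measure = "tanimoto") -> float:
    """Evaluate one similarity measure on overlap components.

    Empty-vs-empty (SA=SB=SC=0) returns 0.0 by convention, with a warning,
    to avoid 0/0.
    """
    sa, sb, sc = c.SA, c.SB, c.SC
    if sa < 0 or sb < 0 or sc < 0:
        raise ValueError("negative similarity components")
    if sa == 0 and sb == 0 and sc == 0:
        logger.warning("similarity of two empty fingerprints: returning 0 by convention")
        return 0.0
    if measure == "tanimoto":
        return sa / (sa + sb + sc)
    if measure == "dice":
        return 2 * sa / (2 * sa + sb + sc)
    if measure == "cosine":
        denom = math.sqrt((sa + sb) * (sa + sc))
        return sa / denom if denom > 0 else 0.0
    raise ValueError(f"unknown measure: {measure}")


def top_k(reference: MoleculeRecord, db: Iterable[MoleculeRecord], k: int = 500,
          measure: Measure = "tanimoto", scheme: Scheme = "atom-type",
          mode: Optional[Mode] = None, max_distance: int = 6,
          run_id: str = "",
          db_fps: Optional[Sequence[tuple[str, SparseFingerprint]]] = None) -> HitList:
    """Exhaustively scan a database for the k targets most similar to a reference.

    Results are sorted by similarity descending; ties are broken by database
    input order (stable).  If the database is smaller than k, all of it is
    returned.  ``db_fps`` — precomputed (id, fingerprint) pairs under the
    same scheme — avoids refingerprinting the database across runs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ref_fp = fingerprint(reference, scheme=scheme, max_distance=max_distance)
    if db_fps is None:
        db_fps = [(rec.id, fingerprint(rec, scheme=scheme, max_distance=max_distance))
                  for rec in db]
    scored: list[tuple[float, int, str]] = []
    for i, (rec_id, fp) in enumerate(db_fps):
        s = similarity(components(fp, ref_fp, mode=mode), measure)
        scored.append((s, i, rec_id))
    if not scored:
        logger.warning("top_k on empty database: empty hit list")
        return HitList.empty({"reference": reference.id, "measure": measure,
                              "scheme": scheme, "k": k, "run_id": run_id})
    scored.sort(key=lambda t: (-t[0], t[1]))
    top = scored[:k]
    rows = pd.DataFrame(
        {
            "reference_id": reference.id,
            "target_id": [t[2] for t in top],
            "measure": measure,
            "scheme": scheme,
            "similarity": [t[0] for t in top],
            "rank": range(1, len(top) + 1),
            "run_id": run_id,
        }
    )
    return HitList(rows=rows, provenance={"reference": reference.id, "measure": measure,
                                          "scheme": scheme, "k": k, "run_id": run_id})


def run_similarity_battery(references: Sequence[MoleculeRecord],
                           db: Sequence[MoleculeRecord], k: int = 500,
                           measures: Sequence[Measure] = MEASURES,
                           schemes: Sequence[Scheme] = SCHEMES,
                           max_distance: int = 6) -> HitList:
    """One top-k run per (reference x measure x scheme), merged.

    The merged, pre-deduplication row count is
    ``n_ref * n_measures * n_schemes * min(k, len(db))`` — with 5
    references, 3 measures, 2 schemes and k=500 on a large database this is
    the 15,000-row battery.  Every row keeps its run provenance.
    """
    if not references or not measures or not schemes:
        raise ValueError("references, measures and schemes must be non-empty")
    fps_by_scheme = {
        scheme: [(rec.id, fingerprint(rec, scheme=scheme, max_distance=max_distance))
                 for rec in db]
        for scheme in schemes
    }
    frames = []
    for ref, measure, scheme in itertools.product(references, measures, schemes):
        run_id = f"{ref.id}|{measure}|{scheme}"
        hl = top_k(ref, db, k=k, measure=measure, scheme=scheme, run_id=run_id,
                   max_distance=max_distance, db_fps=fps_by_scheme[scheme])
        frames.append(hl.rows)
    rows = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=HitList.COLUMNS)
    return HitList(rows=rows, provenance={"k": k, "measures": list(measures),
                                          "schemes": list(schemes),
                                          "n_references": len(references)})
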