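"""Conformer generation and 3D pharmacophore library screening.

Per molecule: embed up to ``max_confs`` 3D conformers (ETKDG distance
geometry, deterministic under the run seed), estimate a conformer strain
energy with the MMFF94 force field (UFF fallback), discard conformers more
than ``energy_window`` kcal/mol above the per-molecule minimum, perceive
feature points per surviving conformer, run the matcher, and keep the best
match.  Hits are sorted by fit descending; per-stage funnel counts are
recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from rdkit import Chem
from rdkit.Chem import AllChem, rdDistGeom

from ..chem import MoleculeRecord
from .match import MatchResult, match
from .model import PharmacophoreModel
from .perceive import perceive_ligand_features

logger = logging.getLogger(__name__)

__all__ = ["ScreenHit", "ScreenResult", "embed_conformers", "conformer_energies", "screen"]

MAX_CONFS_DEFAULT = 255
ENERGY_WINDOW_DEFAULT = 20.0  # kcal/mol


@dataclass
class ScreenHit:
    record: MoleculeRecord
    result: MatchResult


@dataclass
class ScreenResult:
    hits: list[ScreenHit]
    counts: dict[str, int] = field(default_factory=dict)

    def hit_ids(self) -> list[str]:
        return [h.record.id for h in self.hits]


def _per_molecule_seed(seed: int, index: int) -> int:
    return (seed * 100003 + index * 7919 + 1) % (2 ** 31 - 1)


def embed_conformers(mol: Chem.Mol, max_confs: int, seed: int) -> Chem.Mol:
    """Embed up to max_confs conformers; returns a molecule WITH hydrogens."""
    molH = Chem.AddHs(mol)
    params = rdDistGeom.ETKDGv3()
    params.randomSeed = int(seed)
    params.numThreads = 1
    rdDistGeom.EmbedMultipleConfs(molH, numConfs=max_confs, params=params)
    return molH


def conformer_energies(molH: Chem.Mol) -> Optional[list[float]]:
    """MMFF94 single-point energies per conformer (UFF fallback), kcal/mol."""
    energies: list[float] = []
    props = AllChem.MMFFGetMoleculeProperties(molH)
    for conf in molH.GetConformers():
        ff = None
        if props is not None:
            ff = AllChem.MMFFGetMoleculeForceField(molH, props, confId=conf.GetId())
        if ff is None:
            ff = AllChem.UFFGetMoleculeForceField(molH, confId=conf.GetId())
        if ff is None:
            return None
        energies.append(ff.CalcEnergy())
    return energies


def screen(library: Sequence[MoleculeRecord], model: PharmacophoreModel,
           max_confs: int = MAX_CONFS_DEFAULT,
           energy_window: float = ENERGY_WINDOW_DEFAULT,
           seed: int = 0) -> ScreenResult:
    """Screen a library against a pharmacophore model.

    Returns the per-molecule best matches plus funnel counts: ``input``,
    ``embedded`` (molecules with at least one conformer), ``conformers_kept``
    (conformers surviving the energy window, summed), ``matched``.
    Molecules that fail 3D embedding are skipped with a logged warning.
    """
    counts = {"input": len(library), "embedded": 0, "conformers_kept": 0,
              "matched": 0, "embed_failures": 0}
    hits: list[ScreenHit] = []
    for i, rec in enumerate(library):
        molH = embed_conformers(rec.mol, max_confs, _per_molecule_seed(seed, i))
        if molH.GetNumConformers() == 0:
            counts["embed_failures"] += 1
            logger.warning("%s: 3D embedding failed, skipped", rec.id)
            continue
        counts["embedded"] += 1
        energies = conformer_energies(molH)
        conf_ids = [c.GetId() for c in molH.GetConformers()]
        if energies is not None:
            emin = min(energies)
            conf_ids = [cid for cid, e in zip(conf_ids, energies) if e - emin <= energy_window]
        counts["conformers_kept"] += len(conf_ids)
        heavy = Chem.RemoveHs(molH)
        best: Optional[MatchResult] = None
        for cid in conf_ids:
            try:
                points = perceive_ligand_features(heavy, conf_id=cid)
            except ValueError:
                continue
            res = match(points, model, conformer_id=cid)
            if res is not None and (best is None
                                    or (res.fit, res.mapped_count) > (best.fit, best.mapped_count)):
                best = res
        if best is not None:
            counts["matched"] += 1
            hit_rec = MoleculeRecord(id=rec.id, mol=heavy, source=rec.source,
                                     parent_id=rec.parent_id, labels=dict(rec.labels))
            hits.append(ScreenHit(record=hit_rec, result=best))
    hits.sort(key=lambda h: (-h.result.fit, h.record.id))
    return ScreenResult(hits=hits, counts=counts)
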