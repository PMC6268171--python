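"""Rule-based pharmacophore perception.

Ligand-side perception turns a 3D conformer into typed feature points;
receptor-ligand perception turns a complex into a candidate pharmacophore
model, one feature per detected interaction.

Ligand perception rules (this module's convention — distinct from the
Lipinski donor/acceptor counts used by the filters):

* HBD — N/O heavy atoms carrying at least one hydrogen;
* HBA — oxygens, pyridine-type aromatic nitrogens, and aliphatic nitrogens
  outside amide/positively-charged contexts;
* HY  — centroids of all-carbon rings and of chains of >= 3 aliphatic
  carbons with no heteroatom substituent;
* NI  — centroid of each deprotonatable acid group (carboxyl(ate),
  sulfonate, phosphate, tetrazol(at)e ring);
* PI  — protonatable amines and amidine/guanidine groups (or atoms already
  carrying a positive charge);
* RA  — aromatic ring centroid, with ring normal;
* ZB  — the coordinating-atom centroid of each allowed zinc-binding-group
  match (see :mod:`zbscreen.zbg`).

Interaction geometry for complex perception (defaults, Angstrom/degrees):
hydrogen bond at donor-acceptor heavy-atom distance <= 3.5 with a
donor angle >= 120 where an explicit hydrogen is available; hydrophobic
contact at apolar-apolar distance <= 4.5, contacts clustered by ligand
connectivity; charge pair at <= 5.5; zinc coordination at ligand N/O to
Zn distance <= 2.8 (reported as an HBD-at-zinc candidate for later ZB
customization).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser
from rdkit import Chem

from ..chem import MoleculeRecord
from ..zbg import ZbgMatch, detect_zbg
from .model import (
    DEFAULT_TOLERANCE,
    DEFAULT_TOLERANCE_HY,
    ZINC_PROXIMITY,
    PharmacophoreFeature,
    PharmacophoreModel,
)

logger = logging.getLogger(__name__)

HBOND_DISTANCE = 3.5      # donor-acceptor heavy-atom cutoff, Angstrom
HBOND_ANGLE = 120.0       # minimum D-H...A angle, degrees
HYDROPHOBIC_DISTANCE = 4.5
CHARGE_DISTANCE = 5.5

__all__ = [
    "LigandFeaturePoint", "ReceptorStructure",
    "perceive_ligand_features", "perceive_complex_pharmacophore",
]


@dataclass
class LigandFeaturePoint:
    """A perceived ligand-side feature point."""

    kind: str
    position: np.ndarray
    atoms: tuple[int, ...]
    zbg: Optional[ZbgMatch] = None
    normal: Optional[np.ndarray] = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("feature point position must be finite")


_HBD_SMARTS = Chem.MolFromSmarts("[#7,#8;!H0]")
_HBA_SMARTS = [
    Chem.MolFromSmarts("[#8]"),
    Chem.MolFromSmarts("[nX2;+0]"),
    Chem.MolFromSmarts("[NX3;+0;!$([NX3][CX3]=[OX1])]"),
    Chem.MolFromSmarts("[NX2,NX1;+0]"),
]
_NI_SMARTS = [
    # group SMARTS -> indices of atoms whose centroid is the point
    (Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1,OX1-]"), (1, 2)),
    (Chem.MolFromSmarts("[SX4](=[OX1])(=[OX1])[OX2H1,OX1-]"), (1, 2, 3)),
    (Chem.MolFromSmarts("[PX4](=[OX1])([OX2H1,OX1-])[OX2H1,OX1-]"), (1, 2, 3)),
    (Chem.MolFromSmarts("[nX3H1,nX3-]1nnnc1"), (0, 1, 2, 3, 4)),
]
_PI_SMARTS = [
    (Chem.MolFromSmarts("[NX3;+0;!$([NX3][CX3]=[OX1,SX1,NX2]);!$([NX3]a);!$([NX3]=*)]"), (0,)),
    (Chem.MolFromSmarts("[NX3][CX3]=[NX2]"), (0, 2)),
    (Chem.MolFromSmarts("[N+;!$([N+]~[O-])]"), (0,)),
]


def _positions(mol: Chem.Mol, conf_id: int) -> np.ndarray:
    conf = mol.GetConformer(conf_id)
    return np.array([[p.x, p.y, p.z] for p in
                     (conf.GetAtomPosition(i) for i in range(mol.GetNumAtoms()))])


def _apolar_carbon(atom: Chem.Atom) -> bool:
    if atom.GetSymbol() != "C":
        return False
    return all(n.GetAtomicNum() in (1, 6) for n in atom.GetNeighbors())


def _hy_groups(mol: Chem.Mol) -> list[tuple[int, ...]]:
    """All-carbon rings plus connected aliphatic apolar-carbon chains >= 3."""
    groups: list[tuple[int, ...]] = []
    ring_info = mol.GetRingInfo()
    ring_atoms: set[int] = set()
    for ring in ring_info.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetSymbol() == "C" for i in ring):
            groups.append(tuple(sorted(ring)))
            ring_atoms.update(ring)
    chain = [a.GetIdx() for a in mol.GetAtoms()
             if _apolar_carbon(a) and not a.GetIsAromatic() and a.GetIdx() not in ring_atoms
             and not a.IsInRing()]
    chain_set = set(chain)
    seen: set[int] = set()
    for start in chain:
        if start in seen:
            continue
        comp, stack = [], [start]
        while stack:
            i = stack.pop()
            if i in seen:
                continue
            seen.add(i)
            comp.append(i)
            stack.extend(n.GetIdx() for n in mol.GetAtomWithIdx(i).GetNeighbors()
                         if n.GetIdx() in chain_set and n.GetIdx() not in seen)
        if len(comp) >= 3:
            groups.append(tuple(sorted(comp)))
    return groups


def perceive_ligand_features(rec: MoleculeRecord | Chem.Mol,
                             conf_id: int = -1) -> list[LigandFeaturePoint]:
    """Perceive typed feature points on one 3D conformer.

    Raises ValueError when the molecule has no 3D coordinates.
    """
    mol = rec.mol if isinstance(rec, MoleculeRecord) else rec
    if mol.GetNumConformers() == 0:
        rid = rec.id if isinstance(rec, MoleculeRecord) else "<mol>"
        raise ValueError(f"{rid}: 3D coordinates required for perception")
    pos = _positions(mol, conf_id)
    points: list[LigandFeaturePoint] = []

    for (i,) in mol.GetSubstructMatches(_HBD_SMARTS):
        points.append(LigandFeaturePoint("HBD", pos[i], (i,)))

    acceptors: set[int] = set()
    for patt in _HBA_SMARTS:
        acceptors.update(m[0] for m in mol.GetSubstructMatches(patt))
    for i in sorted(acceptors):
        points.append(LigandFeaturePoint("HBA", pos[i], (i,)))

    for group in _hy_groups(mol):
        points.append(LigandFeaturePoint("HY", pos[list(group)].mean(axis=0), group))

    for patt, centroid_idx in _NI_SMARTS:
        for m in mol.GetSubstructMatches(patt):
            atoms = tuple(m[i] for i in centroid_idx)
            points.append(LigandFeaturePoint("NI", pos[list(atoms)].mean(axis=0), atoms))

    pi_seen: set[tuple[int, ...]] = set()
    for patt, centroid_idx in _PI_SMARTS:
        for m in mol.GetSubstructMatches(patt):
            atoms = tuple(sorted(m[i] for i in centroid_idx))
            if atoms in pi_seen:
                continue
            pi_seen.add(atoms)
            points.append(LigandFeaturePoint("PI", pos[list(atoms)].mean(axis=0), atoms))

    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            centroid = pos[list(ring)].mean(axis=0)
            v1 = pos[ring[1]] - pos[ring[0]]
            v2 = pos[ring[2]] - pos[ring[0]]
            n = np.cross(v1, v2)
            norm = np.linalg.norm(n)
            points.append(LigandFeaturePoint("RA", centroid, tuple(sorted(ring)),
                                             normal=n / norm if norm > 0 else None))

    for zm in detect_zbg(mol):
        centroid = pos[list(zm.coordinating)].mean(axis=0)
        points.append(LigandFeaturePoint("ZB", centroid, zm.coordinating, zbg=zm))

    return points


# ---------------------------------------------------------------------------
# Receptor side

#: Side-chain carbon names treated as apolar contact partners, per residue.
_APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "PHE", "PRO", "MET"}
_POSITIVE_RESIDUES = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
_NEGATIVE_RESIDUES = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


@dataclass
class ReceptorAtom:
    element: str
    name: str
    resname: str
    resseq: int
    coord: np.ndarray


class ReceptorStructure:
    """A light typed-atom view of a receptor parsed from PDB.

    Receptor N atoms are treated as hydrogen-bond donors and O atoms as
    acceptors; apolar side-chain carbons of hydrophobic residues are the
    hydrophobic contact partners.  HETATM records named LIG are treated as
    the bound ligand and excluded; metal HETATMs (ZN) are retained.
    """

    def __init__(self, atoms: list[ReceptorAtom]):
        self.atoms = atoms

    @classmethod
    def from_pdb(cls, source: str | Path, exclude_resnames: tuple[str, ...] = ("LIG", "HOH")):
        text = Path(source).read_text() if isinstance(source, Path) else source
        if isinstance(source, str) and "\n" not in source and Path(source).exists():
            text = Path(source).read_text()
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("receptor", StringIO(text))
        atoms = []
        for atom in structure.get_atoms():
            res = atom.get_parent()
            resname = res.get_resname().strip()
            if resname in exclude_resnames:
                continue
            atoms.append(ReceptorAtom(
                element=(atom.element or "").strip().upper() or atom.get_name()[0],
                name=atom.get_name().strip(),
                resname=resname,
                resseq=res.get_id()[1],
                coord=np.asarray(atom.get_coord(), dtype=float),
            ))
        return cls(atoms)

    def zinc_position(self) -> Optional[np.ndarray]:
        for a in self.atoms:
            if a.element == "ZN":
                return a.coord
        return None

    def acceptors(self) -> list[ReceptorAtom]:
        return [a for a in self.atoms if a.element == "O"]

    def donors(self) -> list[ReceptorAtom]:
        return [a for a in self.atoms if a.element == "N"]

    def apolar_carbons(self) -> list[ReceptorAtom]:
        return [a for a in self.atoms
                if a.element == "C" and a.resname in _APOLAR_RESIDUES
                and a.name not in ("CA", "C")]

    def charged_centers(self, sign: str) -> list[tuple[str, np.ndarray]]:
        table = _POSITIVE_RESIDUES if sign == "positive" else _NEGATIVE_RESIDUES
        centers = []
        by_res: dict[tuple[str, int], list[ReceptorAtom]] = {}
        for a in self.atoms:
            if a.resname in table and a.name in table[a.resname]:
                by_res.setdefault((a.resname, a.resseq), []).append(a)
        for (resname, resseq), atoms in sorted(by_res.items()):
            coord = np.mean([a.coord for a in atoms], axis=0)
            centers.append((f"{resname}{resseq}", coord))
        return centers


def _donor_angle_ok(mol: Chem.Mol, pos: np.ndarray, donor_idx: int,
                    acceptor_xyz: np.ndarray) -> bool:
    """D-H...A angle >= HBOND_ANGLE; distance-only if no explicit H."""
    hydrogens = [n.GetIdx() for n in mol.GetAtomWithIdx(donor_idx).GetNeighbors()
                 if n.GetAtomicNum() == 1]
    if not hydrogens:
        return True
    for h in hydrogens:
        v1 = pos[donor_idx] - pos[h]
        v2 = acceptor_xyz - pos[h]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
        if angle >= HBOND_ANGLE:
            return True
    return False


def perceive_complex_pharmacophore(receptor: ReceptorStructure,
                                   ligand: MoleculeRecord,
                                   conf_id: int = -1) -> PharmacophoreModel:
    """Derive a candidate pharmacophore model from a receptor-ligand complex.

    One feature per detected interaction, positioned on the ligand side and
    projected to the receptor partner, annotated with the partner residue.
    Ligand N/O atoms coordinating the zinc are reported as HBD candidates
    annotated ``Zn`` (zinc-proximal), ready for :func:`customize_zb`.
    An interaction-free complex yields an empty model with a warning.
    """
    mol = ligand.mol
    if mol.GetNumConformers() == 0:
        raise ValueError(f"{ligand.id}: ligand must carry 3D coordinates")
    pos = _positions(mol, conf_id)
    zn = receptor.zinc_position()

    features: list[PharmacophoreFeature] = []
    counter: dict[str, int] = {}

    def add(kind: str, center, annotation: str, projection=None, tolerance=None):
        counter[kind] = counter.get(kind, 0) + 1
        tol = tolerance if tolerance is not None else (
            DEFAULT_TOLERANCE_HY if kind == "HY" else DEFAULT_TOLERANCE)
        features.append(PharmacophoreFeature(
            id=f"{kind}{counter[kind]}", kind=kind, center=np.asarray(center, float),
            tolerance=tol, projection=projection, annotation=annotation))

    donor_idx = [m[0] for m in mol.GetSubstructMatches(_HBD_SMARTS)]
    acceptor_idx: set[int] = set()
    for patt in _HBA_SMARTS:
        acceptor_idx.update(m[0] for m in mol.GetSubstructMatches(patt))

    # zinc coordination first; coordinating atoms are excluded from plain H-bonds
    zinc_atoms: set[int] = set()
    if zn is not None:
        for a in mol.GetAtoms():
            i = a.GetIdx()
            if a.GetSymbol() in ("N", "O") and np.linalg.norm(pos[i] - zn) <= ZINC_PROXIMITY:
                zinc_atoms.add(i)
                add("HBD", pos[i], "Zn", projection=(zn, 30.0))

    for d in donor_idx:
        if d in zinc_atoms:
            continue
        for ra in receptor.acceptors():
            if np.linalg.norm(pos[d] - ra.coord) <= HBOND_DISTANCE \
                    and _donor_angle_ok(mol, pos, d, ra.coord):
                add("HBD", pos[d], f"{ra.resname}{ra.resseq}", projection=(ra.coord, 30.0))
                break

    for a in sorted(acceptor_idx):
        if a in zinc_atoms:
            continue
        for rd in receptor.donors():
            if np.linalg.norm(pos[a] - rd.coord) <= HBOND_DISTANCE:
                add("HBA", pos[a], f"{rd.resname}{rd.resseq}", projection=(rd.coord, 30.0))
                break

    apolar_rec = receptor.apolar_carbons()
    contact_atoms = []
    for group in _hy_groups(mol):
        in_contact = [i for i in group
                      if any(np.linalg.norm(pos[i] - c.coord) <= HYDROPHOBIC_DISTANCE
                             for c in apolar_rec)]
        if in_contact:
            residues = sorted({f"{c.resname}{c.resseq}" for c in apolar_rec
                               if any(np.linalg.norm(pos[i] - c.coord) <= HYDROPHOBIC_DISTANCE
                                      for i in in_contact)})
            add("HY", pos[in_contact].mean(axis=0), "/".join(residues))
            contact_atoms.extend(in_contact)

    lig_points = perceive_ligand_features(ligand, conf_id=conf_id)
    for p in lig_points:
        if p.kind == "NI":
            for resid, center in receptor.charged_centers("positive"):
                if np.linalg.norm(p.position - center) <= CHARGE_DISTANCE:
                    add("NI", p.position, resid)
                    break
        elif p.kind == "PI":
            for resid, center in receptor.charged_centers("negative"):
                if np.linalg.norm(p.position - center) <= CHARGE_DISTANCE:
                    add("PI", p.position, resid)
                    break

    if not features:
        logger.warning("%s: no receptor-ligand interactions found; empty model", ligand.id)
    metadata = {"source_structure": ligand.source or "complex",
                "ligand_id": ligand.id}
    if zn is not None:
        metadata["zinc"] = [float(x) for x in zn]
    return PharmacophoreModel(
        features=features,
        min_required=min(4, len(features)) if features else 0,
        mandatory_ids=[],
        metadata=metadata,
    )
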