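"""Deterministic synthetic-data generators.

Every input the screening funnel consumes can be generated here with known
ground truth, so all stages are testable offline:

* :func:`synth_library` — a drug-like small-molecule library assembled from
  a fragment grammar (ring scaffolds x substituents) with controllable
  fractions of zinc-binding-group-bearing, excluded-group-bearing and
  rule-violating molecules;
* :func:`toy_conformer` — a pseudo-ligand "feature skeleton": minimal
  chemical fragments placed so its perceived feature points sit within a
  chosen jitter of exactly k pharmacophore feature centers;
* :func:`mini_complex` — a miniature zinc-site receptor-ligand complex in
  PDB format realizing a known set of interactions (one hydrogen bond, one
  hydrophobic contact, one zinc coordination);
* :func:`synth_score_table` — a six-function docking score table with a
  designated plant candidate that dominates on every score.

All generators are pure functions of their arguments (seed included); score
ranges and fragment choices are invented but documented, and only ordering
or count properties should ever be asserted on them, never absolute values.
"""

from __future__ import annotations

import math
import random
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from .chem import MoleculeRecord
from .pharmacophore.model import PharmacophoreModel
from .zbg import ZBG_CLASSES

__all__ = ["synth_library", "toy_conformer", "mini_complex", "synth_score_table",
           "fixture_binders", "FIXTURE_BINDERS"]

# --------------------------------------------------------------------------
# Fragment grammar

# scaffolds with a primary ({r1}) and an optional secondary ({r2}) site;
# an unused site collapses to an unsubstituted position.  Scaffold rings use
# SMILES ring-closure digits 1-2, substituent rings digit 3.
_SCAFFOLDS = [
    "c1cc({r2})cc({r1})c1",           # benzene, meta-disubstituted
    "C1CC({r2})CC({r1})C1",           # cyclohexane, 1,3
    "c1cc({r2})nc({r1})c1",           # pyridine, 2,6
    "c1ccc2cc({r1})c({r2})cc2c1",     # naphthalene, 2,3
    "C1CN({r2})CCC1{r1}",             # piperidine
    "c1cc({r2})sc1{r1}",              # thiophene
    "c1oc({r1})cc1{r2}",              # furan
]

_PLAIN_SUBS = ["C", "CC", "CCC", "OC", "F", "Cl", "NC(C)=O", "C#N",
               "OCC", "C(C)C", "c3ccccc3", "N3CCCC3", "C(F)(F)F", "CNC",
               "OCCC", "CCl"]

# one attachment-ready substituent per allowed ZBG class, in class order
_ZBG_SUBS = {
    "carboxyl": "C(=O)O",
    "phosphate": "OP(=O)(O)O",
    "imidazole": "c3cnc[nH]3",
    "triazole-123": "c3cn[nH]n3",
    "triazole-124": "c3nc[nH]n3",
    "tetrazole": "c3nnn[nH]3",
    "thiadiazole": "c3nncs3",
    "hydroxy-oxo-12": "C(=O)CO",
}

_EXCLUDED_SUBS = {"hydroxamate": "C(=O)NO", "thiol": "S"}

# decorations engineered to violate at least one drug-likeness rule
_VIOLATION_SUBS = [
    "CCCCCCCCCCCCCCCC",            # hexadecyl: clogp > 5 and rotb > 10
    "C(O)C(O)C(O)C(O)C(O)CO",      # hexaol: hbd > 5
]


def _assemble(rng: random.Random, r1: str, r2: Optional[str]) -> str:
    scaffold = rng.choice(_SCAFFOLDS)
    smi = scaffold.format(r1=r1, r2=r2 or "")
    return smi.replace("()", "")


def synth_library(n: int, seed: int = 0, zbg_fraction: float = 0.5,
                  violation_fraction: float = 0.2) -> list[MoleculeRecord]:
    """Generate a labeled synthetic screening library.

    The first ``round(n * zbg_fraction)`` molecules carry exactly one
    allowed zinc-binding group (classes cycled); a disjoint share of up to
    5% carries an excluded group (hydroxamate or thiol); a
    ``violation_fraction`` share is decorated to violate at least one
    Lipinski/Veber rule.  Ground truth is recorded in each record's
    ``labels`` dict: ``zbg_class`` (or None), ``excluded`` and ``violates``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = random.Random(seed)
    n_zbg = round(n * zbg_fraction)
    n_excl = min(round(0.05 * n), n - n_zbg)
    vio = set(rng.sample(range(n), round(n * violation_fraction)))

    records: list[MoleculeRecord] = []
    excl_names = sorted(_EXCLUDED_SUBS)
    for i in range(n):
        labels: dict = {"zbg_class": None, "excluded": False, "violates": i in vio}
        if i < n_zbg:
            cls = ZBG_CLASSES[i % len(ZBG_CLASSES)]
            labels["zbg_class"] = cls
            r1 = _ZBG_SUBS[cls]
        elif i < n_zbg + n_excl:
            labels["excluded"] = True
            r1 = _EXCLUDED_SUBS[excl_names[i % len(excl_names)]]
        else:
            r1 = rng.choice(_PLAIN_SUBS)
        r2 = rng.choice(_VIOLATION_SUBS) if i in vio else (
            rng.choice(_PLAIN_SUBS) if rng.random() < 0.5 else None)
        smi = _assemble(rng, r1, r2)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # pragma: no cover - grammar is closed
            raise RuntimeError(f"fragment grammar produced invalid SMILES: {smi}")
        records.append(MoleculeRecord(id=f"syn{i:05d}", mol=mol, source="synth_library",
                                      labels=labels))
    return records


#: Engineered binder molecules for the packaged Glo-1 model: a zinc-binding
#: azole core carrying a biphenyl arm that reaches both hydrophobic spheres
#: and a short polar arm that can reach a donor feature.  Constructed so at
#: least one accessible conformer maps >= 4 features including the
#: mandatory ZB and adjacent HY.
FIXTURE_BINDERS = [
    ("OCCn1nnnc1-c1ccc(-c2ccccc2)cc1", "binder-tetrazole"),
    ("OCCCn1nnnc1-c1ccc(-c2ccccc2)cc1", "binder-tetrazole-2"),
    ("NCCn1nnnc1-c1ccc(-c2ccccc2)cc1", "binder-tetrazole-3"),
    ("OCCc1nnc(-c2ccc(-c3ccccc3)cc2)s1", "binder-thiadiazole"),
]


def fixture_binders() -> list[MoleculeRecord]:
    """Records for the engineered Glo-1 binder fixtures."""
    out = []
    for smi, name in FIXTURE_BINDERS:
        mol = Chem.MolFromSmiles(smi)
        out.append(MoleculeRecord(id=name, mol=mol, source="fixture_binders",
                                  labels={"binder": True}))
    return out


# --------------------------------------------------------------------------
# Toy conformers ("feature skeletons")

def _frag_with_coords(smiles: str, coords: list[tuple[float, float, float]]) -> Chem.Mol:
    """Heavy-atom fragment with explicit coordinates; hydrogens stay implicit."""
    mol = Chem.MolFromSmiles(smiles)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, (x, y, z) in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(x, y, z))
    mol.AddConformer(conf, assignId=True)
    Chem.SanitizeMol(mol)
    return mol


def _pentagon(center: np.ndarray, anchor_index: int, radius: float = 1.17) -> list[np.ndarray]:
    """Five coplanar points (xy-plane) with point ``anchor_index`` at `center`."""
    pts = []
    for j in range(5):
        ang = 2 * math.pi * j / 5
        pts.append(np.array([radius * math.cos(ang), radius * math.sin(ang), 0.0]))
    shift = center - pts[anchor_index]
    return [p + shift for p in pts]


def _fragment_for(kind: str, target: np.ndarray) -> tuple[str, list[tuple[float, float, float]]]:
    t = np.asarray(target, float)
    if kind == "ZB":
        # imidazole, pyridine-type N (SMILES atom 4 in c1c[nH]cc1? use explicit order)
        # SMILES "c1cnc[nH]1": atoms c0 c1 n2 c3 n4(H); coordinating pyridine N = n2
        pts = _pentagon(t, anchor_index=2)
        return "c1cnc[nH]1", [tuple(p) for p in pts]
    if kind == "HY":
        offs = [(-1.26, 0.26, 0.0), (0.0, -0.52, 0.0), (1.26, 0.26, 0.0)]
        return "CCC", [tuple(t + np.array(o)) for o in offs]
    if kind == "HBD":
        return "O", [tuple(t)]  # water oxygen: donor (and acceptor) at the target
    if kind == "HBA":
        return "COC", [tuple(t + np.array([-1.2, 0.6, 0.0])), tuple(t),
                       tuple(t + np.array([1.2, 0.6, 0.0]))]
    if kind == "NI":
        # methanesulfonate: NI point is the centroid of the three oxygens
        o_offs = [np.array([1.2 * math.cos(a), 1.2 * math.sin(a), 0.0])
                  for a in (0.0, 2 * math.pi / 3, 4 * math.pi / 3)]
        s = t + np.array([0.0, 0.0, 0.81])
        c = s + np.array([0.0, 0.0, 1.80])
        # SMILES "CS(=O)(=O)[O-]": C0 S1 O2 O3 O4
        return "CS(=O)(=O)[O-]", [tuple(c), tuple(s)] + [tuple(t + o) for o in o_offs]
    if kind == "PI":
        return "CN", [tuple(t + np.array([0.0, 1.47, 0.0])), tuple(t)]
    if kind == "RA":
        pts = []
        for j in range(6):
            ang = 2 * math.pi * j / 6
            pts.append(tuple(t + np.array([1.39 * math.cos(ang), 1.39 * math.sin(ang), 0.0])))
        return "c1ccccc1", pts
    raise ValueError(f"no toy fragment for kind {kind}")


def toy_conformer(model: PharmacophoreModel, k: int, jitter: float = 0.0,
                  seed: int = 0) -> tuple[MoleculeRecord, list[str]]:
    """Build a pseudo-ligand matching exactly k features of a model.

    Features are chosen mandatory-first (so any k >= 2 includes the
    mandatory pair), then in model order.  Each chosen feature gets a
    minimal chemical fragment whose perceived point of the right kind sits
    within ``jitter`` of the feature center; unchosen features have no
    same-kind point anywhere near them.  Returns the record and the list of
    intended feature ids.
    """
    if not 0 <= k <= len(model.features):
        raise ValueError("k must be between 0 and the model feature count")
    rng = random.Random(seed)
    chosen: list[str] = [fid for fid in model.mandatory_ids][:k]
    for f in model.features:
        if len(chosen) >= k:
            break
        if f.id not in chosen:
            chosen.append(f.id)

    frags: list[Chem.Mol] = []
    for fid in chosen:
        f = model.feature(fid)
        offset = np.zeros(3)
        if jitter > 0:
            v = np.array([rng.gauss(0, 1) for _ in range(3)])
            offset = jitter * v / np.linalg.norm(v)
        smiles, coords = _fragment_for(f.kind, f.center + offset)
        frags.append(_frag_with_coords(smiles, coords))

    if not frags:
        mol = _frag_with_coords("C", [(0.0, 0.0, 0.0)])
    else:
        mol = frags[0]
        for frag in frags[1:]:
            mol = Chem.CombineMols(mol, frag)
    Chem.SanitizeMol(mol)
    rec = MoleculeRecord(id=f"toy-k{k}-s{seed}", mol=mol, source="toy_conformer",
                         labels={"intended_features": list(chosen)})
    return rec, list(chosen)


# --------------------------------------------------------------------------
# Miniature receptor-ligand complex

_PDB_ATOM = ("{kind:<6}{serial:>5} {name:<4}{alt:1}{resname:<3} {chain:1}"
             "{resseq:>4}{icode:1}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
             "          {element:>2}\n")


def _pdb_line(kind, serial, name, resname, chain, resseq, xyz, element):
    return _PDB_ATOM.format(kind=kind, serial=serial, name=name, alt=" ", resname=resname,
                            chain=chain, resseq=resseq, icode=" ", x=xyz[0], y=xyz[1],
                            z=xyz[2], occ=1.0, b=0.0, element=element)


def mini_complex(seed: int = 0) -> tuple[str, MoleculeRecord, dict]:
    """A ~20-atom synthetic zinc-site complex with known interactions.

    Returns (pdb_text, ligand_record, ground_truth).  The ligand is
    pentane-1,5-diol: one hydroxyl donates a hydrogen bond to a serine
    side-chain oxygen (2.9 A, ~165 deg), the other coordinates the zinc
    (2.3 A), and the central three carbons contact a leucine side chain
    (hydrophobic).  Ground truth lists the perceived feature kinds:
    one zinc-proximal HBD, one plain HBD, one HY.
    """
    del seed  # the complex is a fixed deterministic fixture
    zn = np.array([0.0, 0.0, 0.0])
    lig_heavy = {
        "O2": np.array([0.0, 0.0, 2.3]),
        "C5": np.array([0.0, 1.2, 3.0]),
        "C4": np.array([0.0, 2.6, 2.6]),
        "C3": np.array([0.0, 3.7, 3.6]),
        "C2": np.array([0.0, 5.1, 3.2]),
        "C1": np.array([0.0, 6.2, 4.2]),
        "O1": np.array([0.0, 7.5, 3.7]),
    }
    ser_og = np.array([0.0, 9.82, 1.96])
    # hydroxyl hydrogen placed 10 degrees off the O1->OG line (angle ~166 deg)
    d = ser_og - lig_heavy["O1"]
    d /= np.linalg.norm(d)
    perp = np.cross(d, np.array([1.0, 0.0, 0.0]))
    perp /= np.linalg.norm(perp)
    h1 = lig_heavy["O1"] + 0.97 * (math.cos(math.radians(10)) * d
                                   + math.sin(math.radians(10)) * perp)
    h2 = lig_heavy["O2"] + 0.97 * np.array([0.0, -0.8, -0.6]) / math.hypot(0.8, 0.6)

    receptor_atoms = [
        ("ZN", "ZN", "A", 1, zn, "ZN"),
        ("OG", "SER", "A", 2, ser_og, "O"),
        ("CB", "SER", "A", 2, np.array([0.3, 9.9, 3.4]), "C"),
        ("CA", "SER", "A", 2, np.array([0.5, 11.3, 3.9]), "C"),
        ("N", "SER", "A", 2, np.array([1.2, 12.1, 2.9]), "N"),
        ("C", "SER", "A", 2, np.array([1.3, 11.3, 5.2]), "C"),
        ("O", "SER", "A", 2, np.array([1.8, 12.4, 5.6]), "O"),
        ("CD1", "LEU", "A", 3, np.array([0.0, 3.8, 7.0]), "C"),
        ("CG", "LEU", "A", 3, np.array([0.8, 4.0, 8.2]), "C"),
        ("CD2", "LEU", "A", 3, np.array([2.2, 3.7, 7.9]), "C"),
        ("CB", "LEU", "A", 3, np.array([0.9, 5.0, 9.2]), "C"),
        ("CA", "LEU", "A", 3, np.array([2.0, 5.5, 10.0]), "C"),
        ("N", "LEU", "A", 3, np.array([2.2, 6.9, 10.2]), "N"),
        ("C", "LEU", "A", 3, np.array([2.9, 4.8, 11.0]), "C"),
        ("O", "LEU", "A", 3, np.array([3.5, 5.4, 11.9]), "O"),
    ]
    lines = []
    serial = 1
    for name, resname, chain, resseq, xyz, element in receptor_atoms:
        kind = "HETATM" if resname == "ZN" else "ATOM"
        lines.append(_pdb_line(kind, serial, name, resname, chain, resseq, xyz, element))
        serial += 1
    for name, xyz in lig_heavy.items():
        lines.append(_pdb_line("HETATM", serial, name, "LIG", "B", 9, xyz,
                               name[0]))
        serial += 1
    lines.append("END\n")
    pdb_text = "".join(lines)

    # ligand molecule: OCCCCCO with explicit hydroxyl hydrogens
    rw = Chem.RWMol()
    order = ["O2", "C5", "C4", "C3", "C2", "C1", "O1"]
    idx = {}
    for name in order:
        a = Chem.Atom("O" if name.startswith("O") else "C")
        a.SetNoImplicit(False)
        idx[name] = rw.AddAtom(a)
    for a, b in zip(order, order[1:]):
        rw.AddBond(idx[a], idx[b], Chem.BondType.SINGLE)
    ih1 = rw.AddAtom(Chem.Atom(1))
    rw.AddBond(idx["O1"], ih1, Chem.BondType.SINGLE)
    ih2 = rw.AddAtom(Chem.Atom(1))
    rw.AddBond(idx["O2"], ih2, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    conf = Chem.Conformer(mol.GetNumAtoms())
    for name in order:
        conf.SetAtomPosition(idx[name], Point3D(*lig_heavy[name]))
    conf.SetAtomPosition(ih1, Point3D(*h1))
    conf.SetAtomPosition(ih2, Point3D(*h2))
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol)
    ligand = MoleculeRecord(id="minilig", mol=mol, source="mini_complex")

    ground_truth = {
        "zinc": [float(x) for x in zn],
        "interactions": [
            {"kind": "HBD", "annotation": "Zn", "ligand_atom": "O2"},
            {"kind": "HBD", "annotation": "SER2", "ligand_atom": "O1"},
            {"kind": "HY", "annotation": "LEU3", "ligand_atoms": ["C2", "C3", "C4"]},
        ],
    }
    return pdb_text, ligand, ground_truth


# --------------------------------------------------------------------------
# Synthetic docking scores

_SCORE_RANGES = {
    "GoldScore": (20.0, 80.0),
    "ChemScore": (20.0, 80.0),
    "ASP": (20.0, 80.0),
    "CHEMPLP": (20.0, 80.0),
    "CDOCKER": (-60.0, 0.0),
    "LibDock": (50.0, 150.0),
}
_HIGHER_BETTER = {"CDOCKER": False}


def synth_score_table(candidates: Sequence[str], seed: int = 0,
                      plant: Optional[str] = None, poses: int = 2) -> tuple[pd.DataFrame, str]:
    """Long-form six-function score table; the plant dominates every score.

    Returns (table, plant_id).  ``plant`` defaults to the first candidate.
    Score ranges are invented plausible ranges per program family; only
    ordering properties should be asserted.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    plant = plant or candidates[0]
    rng = random.Random(seed)
    rows = []
    for cand in candidates:
        for name, (lo, hi) in _SCORE_RANGES.items():
            higher = _HIGHER_BETTER.get(name, True)
            for p in range(poses):
                if cand == plant:
                    v = hi + 5.0 if higher else lo - 5.0
                    v += rng.uniform(0, 1)  # poses differ, dominance retained
                else:
                    v = rng.uniform(lo, hi - 1e-6)
                rows.append({"candidate_id": cand, "pose_id": f"pose{p + 1}",
                             "score_name": name, "value": round(v, 4)})
    return pd.DataFrame(rows), plant
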