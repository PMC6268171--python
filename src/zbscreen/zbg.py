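"""Zinc-binding-group (ZBG) detection.

A selective dictionary of functional groups able to coordinate an
active-site zinc atom.  Exactly eight classes are allowed — carboxyl,
phosphate, imidazole, 1,2,3-triazole, 1,2,4-triazole, tetrazole,
thiadiazole and 1-hydroxy-2-oxo derivatives — while two classically
zinc-avid groups, hydroxamates and thiols, are deliberately excluded
(poor in-vivo absorption, mutagenic hydroxylamine metabolites, taste and
photosensitivity liabilities).  Exclusion patterns veto only their own
atoms: a molecule carrying both a thiol and a carboxyl still reports the
carboxyl.

Patterns live in ``data/zbg_patterns.yaml`` (versioned data, not code).

The chelation geometry check encodes the flavonoid structure-activity
observation that the two chelating oxygens (hydroxyl and ketone) must be
separated by 2.5 +/- 0.5 Angstrom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import yaml
from rdkit import Chem

from .chem import MoleculeRecord

__all__ = ["ZbgMatch", "ZBG_CLASSES", "detect_zbg", "chelation_geometry_ok", "load_patterns"]

ZBG_CLASSES = (
    "carboxyl",
    "phosphate",
    "imidazole",
    "triazole-123",
    "triazole-124",
    "tetrazole",
    "thiadiazole",
    "hydroxy-oxo-12",
)

CHELATION_CENTER = 2.5   # Angstrom
CHELATION_HALF_WIDTH = 0.5


@dataclass(frozen=True)
class ZbgMatch:
    """One detected zinc-binding group.

    ``coordinating`` are the N/O atoms presented to the metal; always a
    subset of ``atoms``.
    """

    zbg_class: str
    atoms: tuple[int, ...]
    coordinating: tuple[int, ...]

    def __post_init__(self):
        if self.zbg_class not in ZBG_CLASSES:
            raise ValueError(f"unknown ZBG class: {self.zbg_class}")
        if not set(self.coordinating) <= set(self.atoms):
            raise ValueError("coordinating atoms must be a subset of matched atoms")


_PATTERNS_CACHE: dict | None = None


def load_patterns() -> dict:
    """Load and compile the versioned pattern dictionary (cached)."""
    global _PATTERNS_CACHE
    if _PATTERNS_CACHE is not None:
        return _PATTERNS_CACHE
    text = resources.files("zbscreen.data").joinpath("zbg_patterns.yaml").read_text()
    raw = yaml.safe_load(text)
    allowed = []
    for cls in ZBG_CLASSES:  # fixed class priority order
        for entry in raw["allowed"][cls]:
            patt = Chem.MolFromSmarts(entry["smarts"])
            if patt is None:  # pragma: no cover - static data
                raise ValueError(f"bad SMARTS for {cls}: {entry['smarts']}")
            allowed.append((cls, patt, entry["coordinating"]))
    excluded = []
    for name, smarts_list in raw["excluded"].items():
        for s in smarts_list:
            patt = Chem.MolFromSmarts(s)
            if patt is None:  # pragma: no cover - static data
                raise ValueError(f"bad SMARTS for exclusion {name}: {s}")
            excluded.append((name, patt))
    _PATTERNS_CACHE = {"version": raw["version"], "allowed": allowed, "excluded": excluded}
    return _PATTERNS_CACHE


def _coordinating_atoms(mol: Chem.Mol, match: tuple[int, ...], spec) -> tuple[int, ...]:
    if spec == "pyridine-n":
        out = []
        for idx in match:
            atom = mol.GetAtomWithIdx(idx)
            if (atom.GetSymbol() == "N" and atom.GetIsAromatic()
                    and atom.GetTotalNumHs() == 0 and atom.GetFormalCharge() <= 0):
                out.append(idx)
        return tuple(out)
    return tuple(match[i] for i in spec)


def detect_zbg(rec: MoleculeRecord | Chem.Mol) -> list[ZbgMatch]:
    """Find all non-overlapping allowed zinc-binding groups in a molecule.

    Hydroxamate and thiol substructures are never reported; their atoms
    additionally veto any allowed match that overlaps them.  Returns an
    empty list when nothing matches.
    """
    mol = rec.mol if isinstance(rec, MoleculeRecord) else rec
    pats = load_patterns()

    vetoed: set[int] = set()
    for _name, patt in pats["excluded"]:
        for match in mol.GetSubstructMatches(patt):
            vetoed.update(match)

    results: list[ZbgMatch] = []
    claimed: set[int] = set()
    for cls, patt, coord_spec in pats["allowed"]:
        for match in mol.GetSubstructMatches(patt):
            atom_set = set(match)
            if atom_set & vetoed:
                continue
            if atom_set & claimed:
                continue
            coordinating = _coordinating_atoms(mol, match, coord_spec)
            if not coordinating:
                continue
            if any(mol.GetAtomWithIdx(i).GetSymbol() not in ("N", "O") for i in coordinating):
                continue
            results.append(ZbgMatch(zbg_class=cls, atoms=tuple(sorted(atom_set)),
                                    coordinating=tuple(sorted(coordinating))))
            claimed |= atom_set
    return results


def chelation_geometry_ok(o1, o2, center: float = CHELATION_CENTER,
                          half_width: float = CHELATION_HALF_WIDTH) -> bool:
    """True iff two chelating atoms are center +/- half_width apart.

    Both interval bounds are inclusive; defaults encode the 2.5 +/- 0.5 A
    hydroxyl/ketone separation required for bidentate zinc chelation.
    """
    d = math.dist(tuple(o1), tuple(o2))
    return center - half_width <= d <= center + half_width
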