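"""Ligand preparation: ionization, tautomer and stereoisomer enumeration.

This stage expresses the chemical forms a structure populates at
physiological pH (window 6.5-8.5) before 3D screening — essential for
correct zinc-coordination chemistry, where e.g. a carboxylate anion or an
alternative azole tautomer presents different coordinating atoms.

Ionization is rule-table based: each entry maps a substructure pattern to a
literature pKa (table below, versioned with the package).  A group is
toggled when both of its protonation states are populated within the pH
window widened by +/- 2 units, i.e. when its pKa falls in
[ph_low - 2, ph_high + 2]; a group whose pKa lies below the window is
emitted deprotonated, above it protonated, with the input form always
retained.  Tautomers come from RDKit's transform-rule tautomer enumerator
(keto-enol, lactam-lactim, azole NH shifts and related 1,3-shifts).
Unassigned stereocenters are enumerated up to 2^4 isomers per molecule.

Output is capped at ``max_forms`` with deterministic priority
ionization > tautomer > stereo; every form links to its parent record id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.EnumerateStereoisomers import (
    EnumerateStereoisomers,
    StereoEnumerationOptions,
)
from rdkit.Chem.MolStandardize import rdMolStandardize

from .chem import MoleculeRecord

logger = logging.getLogger(__name__)

__all__ = ["IonizationRule", "PKA_RULES", "enumerate_forms", "deduplicate"]

MAX_STEREO_CENTERS = 4  # stereo enumeration caps at 2**4 isomers


@dataclass(frozen=True)
class IonizationRule:
    """A substructure pattern with a literature pKa and a toggle action."""

    name: str
    smarts: str          # the matched atom at index `atom_idx` is (de)protonated
    pka: float
    action: str          # "deprotonate" | "protonate"
    atom_idx: int = 0


# Versioned pKa rule table (v1).  Patterns are matched against the neutral
# input; pKa values are generic literature values for the group class.
PKA_RULES: list[IonizationRule] = [
    IonizationRule("carboxylic-acid", "[CX3](=O)[OX2H1]", 4.2, "deprotonate", atom_idx=2),
    IonizationRule("phosphate-OH", "[PX4](=O)[OX2H1]", 2.0, "deprotonate", atom_idx=2),
    IonizationRule("tetrazole-NH", "[nH]1nnnc1", 4.9, "deprotonate", atom_idx=0),
    IonizationRule("phenol", "[c][OX2H1]", 10.0, "deprotonate", atom_idx=1),
    IonizationRule("thiophenol", "[c][SX2H1]", 6.6, "deprotonate", atom_idx=1),
    IonizationRule(
        "aliphatic-amine",
        "[NX3;H2,H1,H0;+0;!$(N[CX3]=[O,S,N]);!$(Na);!$(N=*)]",
        10.5,
        "protonate",
        atom_idx=0,
    ),
    IonizationRule("imidazole-N", "[nX2;+0]1c[nH]cc1", 7.0, "protonate", atom_idx=0),
    IonizationRule("amidine", "[NX3;+0][CX3]=[NX2;+0]", 12.5, "protonate", atom_idx=2),
]


def _apply_toggle(mol: Chem.Mol, atom_idx: int, action: str) -> Optional[Chem.Mol]:
    rw = Chem.RWMol(mol)
    atom = rw.GetAtomWithIdx(atom_idx)
    if action == "deprotonate":
        if atom.GetTotalNumHs() < 1:
            return None
        atom.SetFormalCharge(atom.GetFormalCharge() - 1)
        atom.SetNumExplicitHs(max(atom.GetTotalNumHs() - 1, 0))
        atom.SetNoImplicit(True)
    elif action == "protonate":
        atom.SetFormalCharge(atom.GetFormalCharge() + 1)
        atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
        atom.SetNoImplicit(True)
    else:
        raise ValueError(action)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _ionized_variants(mol: Chem.Mol, ph_low: float, ph_high: float) -> list[Chem.Mol]:
    """Single-group toggles for every rule whose pKa is near the pH window."""
    lo, hi = ph_low - 2.0, ph_high + 2.0
    variants: list[Chem.Mol] = []
    for rule in PKA_RULES:
        patt = Chem.MolFromSmarts(rule.smarts)
        if patt is None:  # pragma: no cover - table is static
            continue
        if not (lo <= rule.pka <= hi):
            # Outside the widened window only one state is populated; if the
            # input is not that state, still emit the dominant form.
            dominant_needs_toggle = (
                (rule.action == "deprotonate" and rule.pka < lo)
                or (rule.action == "protonate" and rule.pka > hi)
            )
            if not dominant_needs_toggle:
                continue
        for match in mol.GetSubstructMatches(patt):
            v = _apply_toggle(mol, match[rule.atom_idx], rule.action)
            if v is not None:
                variants.append(v)
    return variants


_TAUTOMER_ENUM = rdMolStandardize.TautomerEnumerator()


def _tautomer_variants(mol: Chem.Mol, cap: int = 16) -> list[Chem.Mol]:
    try:
        res = _TAUTOMER_ENUM.Enumerate(mol)
    except Exception:  # pragma: no cover - defensive
        return []
    out = []
    for t in res:
        out.append(t)
        if len(out) >= cap:
            break
    return out


def _stereo_variants(mol: Chem.Mol) -> list[Chem.Mol]:
    opts = StereoEnumerationOptions(onlyUnassigned=True, maxIsomers=2 ** MAX_STEREO_CENTERS,
                                    unique=True)
    try:
        return list(EnumerateStereoisomers(mol, options=opts))
    except Exception:  # pragma: no cover - defensive
        return []


def enumerate_forms(rec: MoleculeRecord, ph_low: float = 6.5, ph_high: float = 8.5,
                    max_forms: int = 32) -> list[MoleculeRecord]:
    """Enumerate the ionization/tautomer/stereo forms of one record.

    The input form is always first.  Added forms are deduplicated by
    canonical SMILES and capped at ``max_forms`` in deterministic priority
    order (ionization, then tautomers, then stereoisomers).  Every output
    links to the parent record via ``parent_id``.
    """
    base = rec.mol
    candidates: list[tuple[str, Chem.Mol]] = [("input", base)]
    candidates += [("ionization", m) for m in _ionized_variants(base, ph_low, ph_high)]
    candidates += [("tautomer", m) for m in _tautomer_variants(base)]
    candidates += [("stereo", m) for m in _stereo_variants(base)]

    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    truncated = False
    for origin, mol in candidates:
        smi = Chem.MolToSmiles(mol)
        if smi in seen:
            continue
        seen.add(smi)
        if len(out) >= max_forms:
            truncated = True
            break
        form_id = rec.id if origin == "input" else f"{rec.id}#{len(out)}"
        out.append(MoleculeRecord(id=form_id, mol=mol, source=f"ligprep:{origin}",
                                  parent_id=rec.id))
    if truncated:
        logger.warning("%s: enumeration truncated at max_forms=%d", rec.id, max_forms)
    return out


def prepare_library(records: Sequence[MoleculeRecord], ph_low: float = 6.5,
                    ph_high: float = 8.5, max_forms: int = 32) -> list[MoleculeRecord]:
    """Enumerate forms for a whole library (order-preserving)."""
    out: list[MoleculeRecord] = []
    for rec in records:
        out.extend(enumerate_forms(rec, ph_low=ph_low, ph_high=ph_high, max_forms=max_forms))
    return out


def deduplicate(records: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
    """Unique records by canonical structure key; stable keep-first."""
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    for rec in records:
        key = rec.structure_key()
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out
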