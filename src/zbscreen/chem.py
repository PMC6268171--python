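"""Molecule records, standard-format I/O and physicochemical descriptors.

Every downstream stage of the screening funnel exchanges compounds as
:class:`MoleculeRecord` objects, which wrap a sanitized RDKit molecule
together with a stable identifier and a provenance tag.

Descriptor conventions
----------------------
Two hydrogen-bonding conventions exist in this package and they are *not*
interchangeable:

* the **Lipinski convention** used by the drug-likeness filters: donors are
  N-H and O-H groups, acceptors are all nitrogen and oxygen atoms;
* the **pharmacophore-perception convention** used by the 3D engine
  (see :mod:`zbscreen.pharmacophore.perceive`), which excludes e.g. amide
  nitrogens from the acceptor set.

:func:`compute_descriptors` implements the Lipinski convention.  logP is the
Crippen atom-contribution estimate as shipped with RDKit; TPSA is the
Ertl/Rohde/Selzer topological polar surface area.  Absolute values may
differ from proprietary implementations; within this package they are fixed
and deterministic.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord",
    "DescriptorSet",
    "MoleculeParseError",
    "read_molecules",
    "write_molecules",
    "compute_descriptors",
]


class MoleculeParseError(ValueError):
    """Raised when a molecule file yields no usable records."""


@dataclass
class MoleculeRecord:
    """A single compound: identity, molecular graph, optional 3D coordinates.

    Parameters
    ----------
    id : str
        Identifier, unique within a collection.
    mol : rdkit.Chem.Mol
        Sanitized RDKit molecule.  May carry one or more conformers.
    source : str
        Provenance tag (file of origin, generator name, parent id ...).
    parent_id : str, optional
        For enumerated forms, the id of the record they were derived from.
    """

    id: str
    mol: Chem.Mol
    source: str = ""
    parent_id: Optional[str] = None
    labels: dict = field(default_factory=dict)

    @property
    def atoms(self) -> list[tuple[str, int]]:
        """(element symbol, formal charge) per atom."""
        return [(a.GetSymbol(), a.GetFormalCharge()) for a in self.mol.GetAtoms()]

    @property
    def bonds(self) -> list[tuple[int, int, float]]:
        """(begin index, end index, bond order) per bond."""
        return [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in self.mol.GetBonds()
        ]

    @property
    def coords3d(self) -> Optional[list[tuple[float, float, float]]]:
        """Coordinates of the first conformer in Angstrom, or None."""
        if self.mol.GetNumConformers() == 0:
            return None
        conf = self.mol.GetConformer()
        return [
            (p.x, p.y, p.z)
            for p in (conf.GetAtomPosition(i) for i in range(self.mol.GetNumAtoms()))
        ]

    def smiles(self) -> str:
        """Canonical SMILES (isomeric, with charges)."""
        return Chem.MolToSmiles(self.mol)

    def structure_key(self) -> str:
        """Canonical structure key used for deduplication."""
        return Chem.MolToSmiles(self.mol)


@dataclass(frozen=True)
class DescriptorSet:
    """Physicochemical descriptors used by the drug-likeness filters.

    mw is in g/mol, tpsa in Angstrom^2; the rest are unitless counts or the
    Crippen logP estimate.
    """

    mw: float
    clogp: float
    hbd: int
    hba: int
    rotb: int
    tpsa: float


def _open_text(path: Path) -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _open_binary(path: Path) -> IO[bytes]:
    if path.suffix == ".gz":
        return gzip.open(path, "rb")
    return open(path, "rb")


def _infer_format(path: Path) -> str:
    name = path.name[:-3] if path.suffix == ".gz" else path.name
    if name.endswith((".smi", ".smiles", ".txt")):
        return "smiles"
    if name.endswith((".sdf", ".mol", ".sd")):
        return "sdf"
    raise ValueError(f"cannot infer molecule format from file name: {path.name}")


def _iter_smiles(handle: IO[str], source: str) -> Iterator[tuple[Optional[Chem.Mol], str, int]]:
    n = 0
    for lineno, line in enumerate(handle, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        n += 1
        mol_id = parts[1].strip() if len(parts) > 1 else f"{source}:{n}"
        yield Chem.MolFromSmiles(smiles), mol_id, lineno


def read_molecules(path: str | Path, format: Optional[str] = None) -> list[MoleculeRecord]:
    """Read a compound collection from a SMILES (.smi) or SDF (V2000) file.

    SMILES files hold one whitespace-separated "SMILES id" record per line;
    SDF ids are taken from the title line.  Records without an id are
    auto-assigned sequential ids.  Gzip-compressed files (``.gz`` suffix)
    are read transparently.  Unparseable entries are skipped with a logged
    warning.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    MoleculeParseError
        If no entry parses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    records: list[MoleculeRecord] = []
    skipped = 0
    if fmt == "smiles":
        with _open_text(path) as fh:
            for mol, mol_id, lineno in _iter_smiles(fh, path.name):
                if mol is None:
                    skipped += 1
                    logger.warning("%s line %d: unparseable SMILES, skipped", path, lineno)
                    continue
                records.append(MoleculeRecord(id=mol_id, mol=mol, source=str(path)))
    elif fmt == "sdf":
        with _open_binary(path) as fh:
            supplier = Chem.ForwardSDMolSupplier(fh)
            for i, mol in enumerate(supplier):
                if mol is None:
                    skipped += 1
                    logger.warning("%s entry %d: unparseable SDF record, skipped", path, i + 1)
                    continue
                mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"{path.name}:{i + 1}"
                parent = mol.GetProp("parent_id") if mol.HasProp("parent_id") else None
                records.append(
                    MoleculeRecord(id=mol_id, mol=mol, source=str(path), parent_id=parent)
                )
    else:
        raise ValueError(f"unknown format: {fmt}")
    if not records:
        raise MoleculeParseError(f"zero parseable records in {path}")
    if skipped:
        logger.warning("%s: skipped %d unparseable entries", path, skipped)
    return records


def write_molecules(records: Sequence[MoleculeRecord], path: str | Path,
                    format: Optional[str] = None) -> None:
    """Write records to SMILES or SDF; format inferred from the suffix."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "smiles":
        with _open_text_write(path) as fh:
            for rec in records:
                tail = f" {rec.parent_id}" if rec.parent_id else ""
                fh.write(f"{rec.smiles()} {rec.id}{tail}\n")
    elif fmt == "sdf":
        with _open_text_write(path) as fh:
            writer = Chem.SDWriter(fh)
            for rec in records:
                mol = Chem.Mol(rec.mol)
                mol.SetProp("_Name", rec.id)
                if rec.parent_id:
                    mol.SetProp("parent_id", rec.parent_id)
                writer.write(mol)
            writer.close()
    else:
        raise ValueError(f"unknown format: {fmt}")


def _open_text_write(path: Path) -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "wt")


def compute_descriptors(rec: MoleculeRecord | Chem.Mol) -> DescriptorSet:
    """Compute the Lipinski/Veber descriptor set for one molecule.

    Donors are N-H/O-H group counts and acceptors are N+O atom counts (the
    Lipinski convention).  Rotatable bonds use the strict definition that
    excludes terminal and amide bonds, so ethanol has zero.
    """
    mol = rec.mol if isinstance(rec, MoleculeRecord) else rec
    if mol is None or mol.GetNumAtoms() == 0:
        rid = rec.id if isinstance(rec, MoleculeRecord) else "<mol>"
        raise ValueError(f"cannot compute descriptors for empty molecule {rid}")
    return DescriptorSet(
        mw=Descriptors.MolWt(mol),
        clogp=Crippen.MolLogP(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NOCount(mol),
        rotb=Lipinski.NumRotatableBonds(mol),
        tpsa=Descriptors.TPSA(mol),
    )


def records_from_smiles(pairs: Iterable[tuple[str, str]], source: str = "memory") -> list[MoleculeRecord]:
    """Build records from (smiles, id) pairs; unparseable entries raise."""
    out = []
    for smiles, mol_id in pairs:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise MoleculeParseError(f"unparseable SMILES for {mol_id}: {smiles}")
        out.append(MoleculeRecord(id=mol_id, mol=mol, source=source))
    return out
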