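"""Pharmacophore model types, YAML serialization, ZB customization.

A pharmacophore model is a set of typed, positioned, toleranced features
with a mandatory subset and a minimum match count.  Feature kinds: HBA,
HBD, HY (hydrophobic), NI/PI (negative/positive ionizable), RA (ring
aromatic) and ZB (zinc binder, this package's custom feature kind —
matching against a ZB feature is restricted to ligand points generated by
the zinc-binding-group dictionary).

The packaged Glo-1 model (``data/glo1_model.yaml``) carries seven
features: one ZB oriented to the catalytic zinc, two HY filling the
hydrophobic pocket, two HBD toward Asn103/Thr101 at the active-site
mouth, one HBA toward Lys156 and one NI complementary to Arg122/Arg37;
minimum four features must match and the ZB plus its adjacent HY are
always required.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

FEATURE_KINDS = ("HBA", "HBD", "HY", "NI", "PI", "RA", "ZB")
DIRECTIONAL_KINDS = ("HBA", "HBD", "ZB")

#: Default feature sphere radii in Angstrom.
DEFAULT_TOLERANCE = 1.6
DEFAULT_TOLERANCE_HY = 2.2

ZINC_PROXIMITY = 2.8  # Angstrom; ligand-atom-to-Zn coordination cutoff

__all__ = [
    "PharmacophoreFeature", "PharmacophoreModel", "FEATURE_KINDS",
    "load_model", "save_model", "glo1_model", "customize_zb",
    "DEFAULT_TOLERANCE", "DEFAULT_TOLERANCE_HY", "ZINC_PROXIMITY",
]


@dataclass
class PharmacophoreFeature:
    """One typed feature sphere, optionally directional."""

    id: str
    kind: str
    center: np.ndarray
    tolerance: float = DEFAULT_TOLERANCE
    projection: Optional[tuple[np.ndarray, float]] = None  # (target xyz, angle tol deg)
    annotation: str = ""
    mandatory: bool = False

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind: {self.kind}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        self.center = np.asarray(self.center, dtype=float)
        if self.projection is not None:
            if self.kind not in DIRECTIONAL_KINDS:
                raise ValueError(f"{self.kind} features cannot carry a projection")
            target, ang = self.projection
            self.projection = (np.asarray(target, dtype=float), float(ang))


@dataclass
class PharmacophoreModel:
    """A feature set with matching requirements and provenance metadata."""

    features: list[PharmacophoreFeature]
    min_required: int
    mandatory_ids: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [f.id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError("feature ids must be unique")
        if self.min_required > len(self.features):
            raise ValueError("min_required exceeds feature count")
        missing = set(self.mandatory_ids) - set(ids)
        if missing:
            raise ValueError(f"mandatory ids not in model: {sorted(missing)}")
        n_zb = sum(1 for f in self.features if f.kind == "ZB")
        if n_zb > 1:
            raise ValueError("at most one ZB feature per model")
        for f in self.features:
            f.mandatory = f.id in self.mandatory_ids

    def feature(self, fid: str) -> PharmacophoreFeature:
        for f in self.features:
            if f.id == fid:
                return f
        raise KeyError(fid)

    def kind_histogram(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.features:
            out[f.kind] = out.get(f.kind, 0) + 1
        return out

    @property
    def zinc(self) -> Optional[np.ndarray]:
        z = self.metadata.get("zinc")
        return None if z is None else np.asarray(z, dtype=float)


def _feature_to_dict(f: PharmacophoreFeature) -> dict:
    d = {
        "id": f.id, "kind": f.kind,
        "center": [float(x) for x in f.center],
        "tolerance": float(f.tolerance),
        "annotation": f.annotation,
    }
    if f.projection is not None:
        d["projection"] = {"target": [float(x) for x in f.projection[0]],
                           "angle_tol": float(f.projection[1])}
    return d


def _feature_from_dict(d: dict) -> PharmacophoreFeature:
    proj = None
    if d.get("projection"):
        proj = (d["projection"]["target"], d["projection"].get("angle_tol", 30.0))
    return PharmacophoreFeature(
        id=d["id"], kind=d["kind"], center=d["center"],
        tolerance=d.get("tolerance", DEFAULT_TOLERANCE),
        projection=proj, annotation=d.get("annotation", ""),
    )


def save_model(model: PharmacophoreModel, path: str | Path) -> None:
    doc = {
        "schema": "zbscreen-pharmacophore-1",
        "metadata": model.metadata,
        "min_required": model.min_required,
        "mandatory": list(model.mandatory_ids),
        "features": [_feature_to_dict(f) for f in model.features],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def model_from_dict(doc: dict) -> PharmacophoreModel:
    if doc.get("schema") != "zbscreen-pharmacophore-1":
        raise ValueError(f"unsupported pharmacophore schema: {doc.get('schema')!r}")
    try:
        return PharmacophoreModel(
            features=[_feature_from_dict(d) for d in doc["features"]],
            min_required=int(doc["min_required"]),
            mandatory_ids=list(doc.get("mandatory", [])),
            metadata=dict(doc.get("metadata", {})),
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"corrupt pharmacophore model file: {exc}") from exc


def load_model(path: str | Path) -> PharmacophoreModel:
    doc = yaml.safe_load(Path(path).read_text())
    return model_from_dict(doc)


def glo1_model() -> PharmacophoreModel:
    """Load the packaged seven-feature Glo-1 active-site model."""
    text = resources.files("zbscreen.data").joinpath("glo1_model.yaml").read_text()
    return model_from_dict(yaml.safe_load(text))


def customize_zb(model: PharmacophoreModel, zn: Sequence[float]) -> PharmacophoreModel:
    """Re-type the zinc-oriented HBD feature as the custom ZB feature.

    Receptor-based perception treats the catalytic zinc as a plain
    hydrogen-bond acceptor partner, producing an HBD feature pointed at it;
    this step replaces that single nearest zinc-proximal HBD with a ZB
    feature (position and tolerance retained), restricting its chemistry to
    the allowed zinc-binding-group classes at match time.  Idempotent: a
    model that already carries a zinc-proximal ZB is returned unchanged.
    """
    zn = np.asarray(zn, dtype=float)

    def zinc_distance(f: PharmacophoreFeature) -> float:
        d = float(np.linalg.norm(f.center - zn))
        if f.projection is not None:
            d = min(d, float(np.linalg.norm(f.projection[0] - zn)))
        return d

    out = copy.deepcopy(model)
    for f in out.features:
        if f.kind == "ZB" and zinc_distance(f) <= ZINC_PROXIMITY:
            return out  # already customized
    candidates = [f for f in out.features
                  if f.kind == "HBD" and zinc_distance(f) <= ZINC_PROXIMITY]
    if not candidates:
        raise ValueError("no feature orients to the zinc position")
    nearest = min(candidates, key=zinc_distance)
    nearest.kind = "ZB"
    nearest.annotation = (nearest.annotation + " Zn").strip()
    out.metadata.setdefault("zinc", [float(x) for x in zn])
    return out
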