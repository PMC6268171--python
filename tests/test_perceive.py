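"""Ligand feature perception, complex perception, model handling."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from zbscreen.chem import MoleculeRecord
from zbscreen.pharmacophore import (
    PharmacophoreFeature,
    PharmacophoreModel,
    ReceptorStructure,
    customize_zb,
    glo1_model,
    load_model,
    perceive_complex_pharmacophore,
    perceive_ligand_features,
    save_model,
)
from zbscreen.synth import mini_complex


def embedded(smiles, rid="m", seed=7):
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    AllChem.EmbedMolecule(mol, randomSeed=seed)
    return MoleculeRecord(id=rid, mol=Chem.RemoveHs(mol))


def kinds(points):
    out = {}
    for p in points:
        out[p.kind] = out.get(p.kind, 0) + 1
    return out


# --- ligand perception ---------------------------------------------------------

def test_benzene_is_one_aromatic_and_one_hydrophobic_point():
    pts = perceive_ligand_features(embedded("c1ccccc1"))
    k = kinds(pts)
    assert k.get("RA") == 1 and k.get("HY") == 1
    assert "HBD" not in k and "HBA" not in k


def test_acetate_yields_ni_and_zb_at_carboxylate_centroid():
    rec = embedded("CC(=O)[O-]")
    pts = perceive_ligand_features(rec)
    ni = [p for p in pts if p.kind == "NI"]
    zb = [p for p in pts if p.kind == "ZB"]
    assert len(ni) == 1 and len(zb) == 1
    assert np.allclose(ni[0].position, zb[0].position, atol=1e-6)
    assert zb[0].zbg.zbg_class == "carboxyl"


def test_methane_has_no_feature_points():
    assert perceive_ligand_features(embedded("C")) == []


def test_perception_requires_coordinates():
    rec = MoleculeRecord(id="flat", mol=Chem.MolFromSmiles("CCO"))
    with pytest.raises(ValueError, match="3D coordinates"):
        perceive_ligand_features(rec)


def test_feature_point_atom_indices_are_valid():
    rec = embedded("OCCc1nnc(-c2ccccc2)s1")
    n = rec.mol.GetNumAtoms()
    for p in perceive_ligand_features(rec):
        assert all(0 <= i < n for i in p.atoms)
        assert np.all(np.isfinite(p.position))


# --- complex perception --------------------------------------------------------

def test_mini_complex_recovers_ground_truth_kinds(complex_fixture):
    pdb, ligand, truth = complex_fixture
    receptor = ReceptorStructure.from_pdb(pdb)
    model = perceive_complex_pharmacophore(receptor, ligand)
    got = sorted((f.kind, f.annotation) for f in model.features)
    want = sorted((i["kind"], i["annotation"]) for i in truth["interactions"])
    assert got == want


def test_complex_perception_is_frame_invariant(complex_fixture):
    pdb, ligand, _ = complex_fixture
    shift = np.array([10.0, 0.0, 0.0])
    shifted_pdb_lines = []
    for line in pdb.splitlines(keepends=True):
        if line.startswith(("ATOM", "HETATM")):
            x = float(line[30:38]) + shift[0]
            line = line[:30] + f"{x:8.3f}" + line[38:]
        shifted_pdb_lines.append(line)
    mol = Chem.Mol(ligand.mol)
    conf = mol.GetConformer()
    for i in range(mol.GetNumAtoms()):
        p = conf.GetAtomPosition(i)
        conf.SetAtomPosition(i, type(p)(p.x + shift[0], p.y, p.z))
    shifted_ligand = MoleculeRecord(id=ligand.id, mol=mol)

    base = perceive_complex_pharmacophore(ReceptorStructure.from_pdb(pdb), ligand)
    moved = perceive_complex_pharmacophore(
        ReceptorStructure.from_pdb("".join(shifted_pdb_lines)), shifted_ligand)
    assert [f.kind for f in moved.features] == [f.kind for f in base.features]
    for a, b in zip(base.features, moved.features):
        assert np.allclose(b.center, a.center + shift, atol=1e-3)


def test_customize_zb_retypes_single_zinc_proximal_donor(complex_fixture):
    pdb, ligand, _ = complex_fixture
    receptor = ReceptorStructure.from_pdb(pdb)
    model = perceive_complex_pharmacophore(receptor, ligand)
    zn = receptor.zinc_position()
    out = customize_zb(model, zn)
    assert len(out.features) == len(model.features)
    assert sum(1 for f in out.features if f.kind == "ZB") == 1
    again = customize_zb(out, zn)
    assert [f.kind for f in again.features] == [f.kind for f in out.features]


def test_customize_zb_without_zinc_proximal_feature_errors(complex_fixture):
    pdb, ligand, _ = complex_fixture
    no_zn_pdb = "".join(l for l in pdb.splitlines(keepends=True) if " ZN " not in l)
    receptor = ReceptorStructure.from_pdb(no_zn_pdb)
    model = perceive_complex_pharmacophore(receptor, ligand)
    with pytest.raises(ValueError, match="no feature orients"):
        customize_zb(model, [0.0, 0.0, 0.0])


# --- packaged model and schema -------------------------------------------------

def test_glo1_model_composition(model):
    assert len(model.features) == 7
    assert model.kind_histogram() == {"ZB": 1, "HY": 2, "HBD": 2, "HBA": 1, "NI": 1}
    assert model.min_required == 4
    assert len(model.mandatory_ids) == 2
    mandatory_kinds = {model.feature(fid).kind for fid in model.mandatory_ids}
    assert mandatory_kinds == {"ZB", "HY"}


def test_glo1_mandatory_hy_is_adjacent_to_zb(model):
    zb = next(f for f in model.features if f.kind == "ZB")
    hys = [f for f in model.features if f.kind == "HY"]
    nearest = min(hys, key=lambda f: np.linalg.norm(f.center - zb.center))
    assert nearest.id in model.mandatory_ids


def test_model_yaml_round_trip(tmp_path, model):
    path = tmp_path / "m.yaml"
    save_model(model, path)
    back = load_model(path)
    assert back.kind_histogram() == model.kind_histogram()
    assert back.mandatory_ids == model.mandatory_ids
    for a, b in zip(model.features, back.features):
        assert np.allclose(a.center, b.center) and a.tolerance == b.tolerance


def test_corrupt_model_file_raises_schema_error(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text("schema: something-else\nfeatures: []\n")
    with pytest.raises(ValueError, match="schema"):
        load_model(path)


def test_model_invariants_enforced():
    f = PharmacophoreFeature(id="a", kind="HY", center=[0, 0, 0])
    with pytest.raises(ValueError, match="min_required"):
        PharmacophoreModel(features=[f], min_required=2)
    with pytest.raises(ValueError, match="tolerance"):
        PharmacophoreFeature(id="b", kind="HY", center=[0, 0, 0], tolerance=0.0)
    with pytest.raises(ValueError, match="projection"):
        PharmacophoreFeature(id="c", kind="HY", center=[0, 0, 0],
                             projection=([0, 0, 1], 30.0))
    zb = [PharmacophoreFeature(id=f"z{i}", kind="ZB", center=[i, 0, 0])
          for i in range(2)]
    with pytest.raises(ValueError, match="ZB"):
        PharmacophoreModel(features=zb, min_required=1)
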