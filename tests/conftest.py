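"""Shared fixtures: small molecule panels and generated inputs."""

import pytest

from zbscreen.chem import records_from_smiles
from zbscreen.pharmacophore import glo1_model
from zbscreen.synth import mini_complex, synth_library


@pytest.fixture(scope="session")
def model():
    return glo1_model()


@pytest.fixture(scope="session")
def small_library():
    return synth_library(200, seed=11, zbg_fraction=0.5, violation_fraction=0.2)


@pytest.fixture(scope="session")
def complex_fixture():
    pdb, ligand, truth = mini_complex(0)
    return pdb, ligand, truth


@pytest.fixture()
def simple_records():
    return records_from_smiles([
        ("CCO", "ethanol"),
        ("CCC", "propane"),
        ("c1ccccc1", "benzene"),
        ("CC(=O)O", "acetic_acid"),
        ("C", "methane"),
    ])


# one canonical exemplar per allowed ZBG class
ALLOWED_PANEL = [
    ("CC(=O)O", "carboxyl"),
    ("OP(=O)(O)OC", "phosphate"),
    ("c1c[nH]cn1", "imidazole"),
    ("c1cn[nH]n1", "triazole-123"),
    ("c1nc[nH]n1", "triazole-124"),
    ("c1nnn[nH]1", "tetrazole"),
    ("c1nncs1", "thiadiazole"),
    ("O=c1cc(-c2ccccc2)oc2cccc(O)c12", "hydroxy-oxo-12"),  # 5-hydroxyflavone
]

# hydroxamates and thiols: famous zinc binders, deliberately excluded
EXCLUSION_PANEL = [
    ("CC(=O)NO", "acetohydroxamic acid"),
    ("ON(c1ccccc1)C(N)=O", "reverse hydroxamate (N-hydroxy-N-phenylurea)"),
    ("CCS", "ethanethiol"),
    ("Sc1ccccc1", "thiophenol"),
]
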