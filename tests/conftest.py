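import numpy as np
import pytest

from gep.synthetic import SynthConfig, generate_complex, generate_dataset

TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   1.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.500   0.500  1.00  0.00           C
ATOM      4  N   GLY A   2       3.500   1.000   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       4.500   2.000   1.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.40  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
END
"""

HETERO_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O
HETATM    3 ZN    ZN A 102       6.000   6.000   6.000  1.00  0.00          ZN
ATOM      4  CA  GLY B   1       3.800   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def tiny_pdb_text():
    return TINY_PDB


@pytest.fixture
def altloc_pdb_text():
    return ALTLOC_PDB


@pytest.fixture
def hetero_pdb_text():
    return HETERO_PDB


@pytest.fixture(scope="session")
def icosphere():
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
    return np.asarray(mesh.vertices, float), np.asarray(mesh.faces, int)


@pytest.fixture(scope="session")
def synth_sample():
    return generate_complex(SynthConfig(seed=11), "fixture")


@pytest.fixture(scope="session")
def small_dataset():
    manifest, samples = generate_dataset(12, SynthConfig(seed=7))
    train = [samples[c] for c in manifest.split_ids("train")]
    val = [samples[c] for c in manifest.split_ids("val")]
    test = [samples[c] for c in manifest.split_ids("test")]
    return train, val, test


def random_rigid_transform(rng):
    """Random rotation (optionally improper) + translation."""
    from scipy.stats import special_ortho_group

    rot = special_ortho_group.rvs(3, random_state=rng)
    if rng.random() < 0.5:
        rot = rot @ np.diag([1.0, 1.0, -1.0])  # add a reflection
    shift = rng.uniform(-30, 30, 3)
    return rot, shift
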