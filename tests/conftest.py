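import numpy as np
import pytest

from fifi import synthetic
from fifi.core import FifiConfig


@pytest.fixture(scope="session")
def small_bundle():
    """A small planted-signal screening study shared across tests."""
    return synthetic.make_screening_set(
        n_active=10, n_inactive=90, n_train_active=10, n_train_inactive=30, seed=7
    )


@pytest.fixture(scope="session")
def twin():
    """Twin-residue fixture: same interaction at residue 1 vs residue 2."""
    return synthetic.make_twin_fixture(seed=3)


@pytest.fixture(scope="session")
def default_config():
    return FifiConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


# --- small hand-written PDB fixtures -------------------------------------

GLY_ALA_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.460   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.300   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       3.200   1.400   0.000  1.00  0.00           O
ATOM      5  N   ALA A   2       1.300   2.400   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       1.800   3.700   0.000  1.00  0.00           C
ATOM      7  C   ALA A   2       3.300   3.800   0.000  1.00  0.00           C
ATOM      8  O   ALA A   2       4.000   4.800   0.000  1.00  0.00           O
ATOM      9  CB  ALA A   2       1.100   4.500   1.100  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.460   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA A   1       1.500   0.100   0.000  0.40  0.00           C
ATOM      4  C   ALA A   1       2.000   1.300   0.000  1.00  0.00           C
ATOM      5  O   ALA A   1       3.200   1.400   0.000  1.00  0.00           O
ATOM      6  CB  ALA A   1       1.900  -0.800   1.100  1.00  0.00           C
END
"""

WATER_ALA_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.460   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.300   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       3.200   1.400   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.900  -0.800   1.100  1.00  0.00           C
HETATM    6  O   HOH A 101       8.000   8.000   8.000  1.00  0.00           O
END
"""


@pytest.fixture()
def pdb_file(tmp_path):
    def write(text, name="toy.pdb"):
        path = tmp_path / name
        path.write_text(text)
        return str(path)

    return write
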