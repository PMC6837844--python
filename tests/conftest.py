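import numpy as np
import pytest

from varstab.variants import load_fixture_table


@pytest.fixture(scope="session")
def fixture_table():
    return load_fixture_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


PDB_3RES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.000   0.000   0.000  1.00 10.00           C
ATOM      4  N   GLY A   2       3.000   0.000   0.000  1.00 10.00           N
ATOM      5  CA  GLY A   2       4.000   0.000   0.000  1.00 10.00           C
ATOM      6  C   GLY A   2       5.000   0.000   0.000  1.00 10.00           C
ATOM      7  N   SER A   3       6.000   0.000   0.000  1.00 10.00           N
ATOM      8  CA ASER A   3       6.000   4.000   0.000  0.30 10.00           C
ATOM      9  CA BSER A   3       7.000   0.000   0.000  0.70 10.00           C
TER
END
"""


@pytest.fixture()
def pdb_path(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(PDB_3RES)
    return p
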