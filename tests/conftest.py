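import numpy as np
import pytest

import statepop as sp


@pytest.fixture(scope="session")
def small_library():
    """3-state, 40-residue, 20-conformer synthetic library with truth."""
    cfg = sp.GeneratorConfig(n_states=3, n_res=40, n_conf=20, seed=7)
    lib, ensembles, truth = sp.generate_state_library(cfg)
    return lib, ensembles, truth


@pytest.fixture
def triangle_ensemble():
    """Two conformers: a 3-4-5 and a 5-12-13 right triangle."""
    ids = (("A", 1, "ALA"), ("A", 2, "ALA"), ("A", 3, "ALA"))
    c1 = sp.Conformer(ids, np.array([[0, 0, 0], [3, 0, 0], [0, 4, 0]], float))
    c2 = sp.Conformer(ids, np.array([[0, 0, 0], [5, 0, 0], [0, 12, 0]], float))
    return sp.StateEnsemble("tri", (c1, c2))


PDB_TWO_MODELS = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       2.000   0.000   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       4.000   0.000   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       5.000   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      6  N   ALA A   1       0.000   0.000   1.000  1.00  0.00           N
ATOM      7  CA  ALA A   1       1.000   0.000   1.000  1.00  0.00           C
ATOM      8  CB  ALA A   1       2.000   0.000   1.000  1.00  0.00           C
ATOM      9  N   GLY A   2       4.000   0.000   1.000  1.00  0.00           N
ATOM     10  CA  GLY A   2       5.000   0.000   1.000  1.00  0.00           C
ENDMDL
END
"""


@pytest.fixture
def pdb_two_models():
    return PDB_TWO_MODELS
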