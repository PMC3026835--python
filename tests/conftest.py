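import numpy as np
import pytest

from gnmpath import ToySpec, make_chain
from gnmpath.structure import CalphaChain


def random_chain(n: int, seed: int, box: float = 25.0) -> CalphaChain:
    """Uniform random points in a box; generic non-symmetric test geometry."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box, size=(n, 3))
    return CalphaChain(
        pdb_id="rand",
        chain_id="A",
        res_ids=np.arange(1, n + 1),
        ins_codes=("",) * n,
        res_names=("ALA",) * n,
        coords=coords,
    )


def chain_from_coords(coords, res_ids=None, names=None) -> CalphaChain:
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if res_ids is None:
        res_ids = np.arange(1, n + 1)
    return CalphaChain(
        pdb_id="fix",
        chain_id="A",
        res_ids=np.asarray(res_ids),
        ins_codes=("",) * n,
        res_names=tuple(names) if names else ("GLY",) * n,
        coords=coords,
    )


@pytest.fixture
def ring12():
    return make_chain(ToySpec(kind="ring", n=12))


@pytest.fixture
def helix30():
    return make_chain(ToySpec(kind="helix", n=30))


@pytest.fixture
def clustered40():
    return make_chain(ToySpec(kind="clustered", n=40, seed=3))


ALTLOC_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA AGLY A   2       3.800   0.000   0.000  0.60  0.00           C
ATOM      3  CA BGLY A   2       3.800   1.000   0.000  0.40  0.00           C
ATOM      4  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
TER
END
"""

WATER_HEM_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
TER
HETATM    3  O   HOH A 101      10.000  10.000  10.000  1.00  0.00           O
HETATM    4  O   HOH A 102      12.000  10.000  10.000  1.00  0.00           O
HETATM    5  O   HOH A 103      14.000  10.000  10.000  1.00  0.00           O
HETATM    6  FE  HEM A 201       5.000   5.000   5.000  1.00  0.00          FE
HETATM    7  C1  HEM A 201       6.000   5.000   5.000  1.00  0.00           C
END
"""
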