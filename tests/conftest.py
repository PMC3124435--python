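import numpy as np
import pytest

from mimomap.align import default_substitution_model
from mimomap.patches import Patch, PatchGraph
from mimomap.structure import AMINO_ACIDS, AntigenModel, AtomRecord, ResidueRecord
from mimomap.surface import AccessibilityResult
from mimomap.synth import ToySpec, make_toy_structure

# ---------------------------------------------------------------------------
# hand-written PDB fixtures
# ---------------------------------------------------------------------------

#: GLY-ALA-SER on chain A; GLY has no CB (anchor falls back to CA)
PDB_GAS = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       3.988   2.840   0.000  1.00  0.00           C
ATOM      7  CB  ALA A   2       3.480   3.660   1.190  1.00  0.00           C
ATOM      8  C   ALA A   2       5.500   2.700   0.000  1.00  0.00           C
ATOM      9  O   ALA A   2       6.030   1.590   0.000  1.00  0.00           O
ATOM     10  N   SER A   3       6.200   3.830   0.000  1.00  0.00           N
ATOM     11  CA  SER A   3       7.660   3.830   0.000  1.00  0.00           C
ATOM     12  CB  SER A   3       8.200   4.600   1.210  1.00  0.00           C
ATOM     13  OG  SER A   3       7.800   5.950   1.190  1.00  0.00           O
ATOM     14  C   SER A   3       8.230   5.200   0.000  1.00  0.00           C
ATOM     15  O   SER A   3       7.500   6.200   0.000  1.00  0.00           O
TER
END
"""

#: one ALA whose CB has two alternate locations (A then B)
PDB_ALTLOC = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CB AALA A   1       2.000   1.000   1.000  0.50  0.00           C
ATOM      4  CB BALA A   1       2.000  -1.000  -1.000  0.50  0.00           C
ATOM      5  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      6  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
TER
END
"""

#: selenomethionine (maps to M) followed by a water (dropped)
PDB_MSE_WATER = """\
HETATM    1  N   MSE A   1       0.000   0.000   0.000  1.00  0.00           N
HETATM    2  CA  MSE A   1       1.458   0.000   0.000  1.00  0.00           C
HETATM    3  CB  MSE A   1       2.000   1.300   0.500  1.00  0.00           C
HETATM    4  C   MSE A   1       2.009   1.420   0.000  1.00  0.00           C
HETATM    5  O   MSE A   1       1.251   2.390   0.000  1.00  0.00           O
HETATM    6  O   HOH A 101       9.000   9.000   9.000  1.00  0.00           O
END
"""


@pytest.fixture
def pdb_gas(tmp_path):
    p = tmp_path / "gas.pdb"
    p.write_text(PDB_GAS)
    return p


@pytest.fixture(scope="session")
def subst():
    return default_substitution_model()


@pytest.fixture(scope="session")
def toy_helix():
    return make_toy_structure(ToySpec(n_residues=20, sequence="A" * 20, seed=0))


@pytest.fixture(scope="session")
def toy_coil():
    return make_toy_structure(ToySpec(n_residues=24, geometry="coil", seed=9))


# ---------------------------------------------------------------------------
# ad-hoc model / graph builders
# ---------------------------------------------------------------------------

def model_from_anchors(coords, aas=None, chain="A") -> AntigenModel:
    """Model whose residues are single pseudo-Cβ atoms at given coordinates."""
    coords = np.asarray(coords, float)
    aas = aas or ["A"] * len(coords)
    residues = [
        ResidueRecord(
            chain, i + 1, "", aa,
            [AtomRecord("CB", "C", np.asarray(c, float), 1.70)],
        )
        for i, (c, aa) in enumerate(zip(coords, aas))
    ]
    return AntigenModel(residues, "synthetic-anchors", chain)


def all_surface(model: AntigenModel) -> AccessibilityResult:
    """Fabricated accessibility marking every residue as surface."""
    n = len(model)
    return AccessibilityResult(
        keys=model.keys,
        asa=np.full(n, 50.0),
        rsa=np.full(n, 0.5),
        is_surface=np.ones(n, bool),
        rsa_threshold=0.05,
    )


def make_graph(aas, edges) -> PatchGraph:
    """Bare patch graph from vertex amino acids and an edge list."""
    n = len(aas)
    keys = [("A", i + 1, "") for i in range(n)]
    patch = Patch(center=keys[0], members=list(keys),
                  member_indices=np.arange(n), radius=15.0)
    return PatchGraph(
        patch=patch, vertices=keys, vertex_aa=list(aas),
        edges={(min(i, j), max(i, j)) for i, j in edges}, threshold=6.5,
    )


def random_patch_graph(rng, n, p=0.4, aas=None) -> PatchGraph:
    aas = aas or [AMINO_ACIDS[i] for i in rng.integers(0, 20, n)]
    edges = {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    }
    return make_graph(aas, edges)
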