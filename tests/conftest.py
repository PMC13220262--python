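import numpy as np
import pytest

from cgpathway import CGStructure, EnergyParams, HeteroBead, Residue, make_toy_two_state

TINY_PDB = """\
ATOM      1  N   GLY A   1      -1.200   0.800   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       1.200   0.900   0.100  1.00  0.00           C
ATOM      4  O   GLY A   1       1.100   2.100   0.200  1.00  0.00           O
ATOM      5  N   ALA A   2       2.400   0.300   0.100  1.00  0.00           N
ATOM      6  CA  ALA A   2       3.700   0.950   0.200  1.00  0.00           C
ATOM      7  CB  ALA A   2       4.100   1.300   1.630  1.00  0.00           C
ATOM      8  C   ALA A   2       4.800   0.050  -0.400  1.00  0.00           C
ATOM      9  O   ALA A   2       4.600  -1.150  -0.600  1.00  0.00           O
ATOM     10  N   TRP A   3       6.000   0.650  -0.600  1.00  0.00           N
ATOM     11  CA  TRP A   3       7.200  -0.050  -1.050  1.00  0.00           C
ATOM     12  CB  TRP A   3       7.600   0.500  -2.420  1.00  0.00           C
ATOM     13  CG  TRP A   3       8.800  -0.150  -3.050  1.00  0.00           C
ATOM     14  CD1 TRP A   3       8.900  -1.400  -3.600  1.00  0.00           C
ATOM     15  CD2 TRP A   3      10.100   0.420  -3.200  1.00  0.00           C
ATOM     16  NE1 TRP A   3      10.150  -1.650  -4.100  1.00  0.00           N
ATOM     17  CE2 TRP A   3      10.900  -0.550  -3.870  1.00  0.00           C
ATOM     18  CE3 TRP A   3      10.650   1.650  -2.830  1.00  0.00           C
ATOM     19  CZ2 TRP A   3      12.250  -0.350  -4.150  1.00  0.00           C
ATOM     20  CZ3 TRP A   3      11.990   1.850  -3.110  1.00  0.00           C
ATOM     21  CH2 TRP A   3      12.780   0.860  -3.760  1.00  0.00           C
ATOM     22  C   TRP A   3       8.350   0.150  -0.060  1.00  0.00           C
ATOM     23  O   TRP A   3       8.300   1.050   0.780  1.00  0.00           O
HETATM   24  C1  LIG A 101       2.000   5.000   1.000  1.00  0.00           C
HETATM   25  N1  LIG A 101       3.300   5.400   1.200  1.00  0.00           N
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


@pytest.fixture
def toy_pair():
    return make_toy_two_state(24, 10.0, seed=5)


@pytest.fixture
def default_params():
    return EnergyParams()


def random_structure(seed: int, max_res: int = 50, with_hetero: bool = True) -> CGStructure:
    """A random coarse-grained structure for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    names = [
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    ]
    n = int(rng.integers(5, max_res + 1))
    residues = []
    for i in range(n):
        chain = "A" if i < n // 2 else "B"
        name = names[rng.integers(len(names))]
        ca = rng.uniform(-20, 20, 3)
        if name == "GLY":
            centroid, nsc = None, 0
        else:
            centroid = ca + rng.normal(0, 2.0, 3)
            nsc = int(rng.integers(1, 8))
        residues.append(
            Residue(chain, i + 1, "", name, ca, centroid, nsc)
        )
    hetero = []
    if with_hetero and rng.random() < 0.7:
        for k in range(rng.integers(1, 4)):
            hetero.append(
                HeteroBead(
                    f"LIG:{k}",
                    rng.uniform(-15, 15, 3),
                    charge=float(rng.choice([-1.0, -0.5, 0.0, 0.5, 1.0])),
                    radius=float(rng.uniform(1.5, 3.0)),
                )
            )
    return CGStructure(residues, hetero, label=f"rand{seed}")


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-10, 10, 3)
    return R, t
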