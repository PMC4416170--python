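import numpy as np
import pytest

from poseforge.structio import AtomRecord, MoleculeStructure
from poseforge.synthdata import SynthScenario, make_benchmark

PDB_FIXTURE = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.729   6.743  -4.123  1.00  0.00           C
ATOM      4  O   ALA A   1       9.578   7.089  -4.397  1.00  0.00           O
ATOM      5  CB  ALA A   1      11.874   4.618  -4.712  1.00  0.00           C
ATOM      6  H   ALA A   1      10.233   5.737  -6.714  1.00  0.00           H
ATOM      7  N   GLY A   2      11.186   6.972  -2.889  1.00  0.00           N
ATOM      8  CA  GLY A   2      10.422   7.610  -1.817  1.00  0.00           C
ATOM      9  C   GLY A   2      10.203   6.677  -0.630  1.00  0.00           C
ATOM     10  O   GLY A   2      10.982   5.744  -0.402  1.00  0.00           O
ATOM     11  N   SER A   3       9.114   6.937   0.102  1.00  0.00           N
ATOM     12  CA  SER A   3       8.741   6.114   1.245  1.00  0.00           C
ATOM     13  CB  SER A   3       7.336   6.479   1.731  1.00  0.00           C
ATOM     14  OG  SER A   3       7.311   7.841   2.129  1.00  0.00           O
ATOM     15  HB2 SER A   3       6.612   6.321   0.931  1.00  0.00           H
HETATM   16  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O
HETATM   17  C1  LIG A 201       3.000   3.000   3.000  1.00  0.00           C
TER
END
"""


@pytest.fixture
def pdb_file(tmp_path):
    path = tmp_path / "receptor.pdb"
    path.write_text(PDB_FIXTURE)
    return path


def random_structure(rng, n_atoms, elements=("C", "N", "O", "S"), scale=10.0, name="mol"):
    """Random element-typed point cloud used across oracle tests."""
    atoms = [
        AtomRecord(str(rng.choice(elements)), tuple(rng.uniform(-scale, scale, 3)))
        for _ in range(n_atoms)
    ]
    return MoleculeStructure(name, atoms)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_benchmark():
    """Small synthetic benchmark shared by model/evaluation tests."""
    scenario = SynthScenario(n_complexes=40, poses_per_complex=8, seed=123)
    pose_sets, table = make_benchmark(scenario)
    return scenario, pose_sets, table


def split_by_complex(table, n_train):
    ids = table.index.get_level_values("complex_id").unique()
    train = table.loc[table.index.get_level_values("complex_id").isin(ids[:n_train])]
    test = table.loc[table.index.get_level_values("complex_id").isin(ids[n_train:])]
    return train, test
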