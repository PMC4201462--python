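import numpy as np
import pytest

from agomg import (
    AtomRecord,
    ComplexTopology,
    Role,
    SimulationBox,
    SyntheticSystemSpec,
    Trajectory,
    generate_complex,
    toy_param_table,
)

ROLE_MAP = {"A": "protein", "G": "guide_rna", "T": "target_rna", "M": "ion"}


@pytest.fixture(scope="session")
def default_spec():
    """The full-size emulated system: 682 residues, 18 missing, high group."""
    return SyntheticSystemSpec(group="high", n_frames=10, seed=11)


@pytest.fixture(scope="session")
def default_complex(default_spec):
    return generate_complex(default_spec)


@pytest.fixture(scope="session")
def tiny_spec():
    """Desk-scale system for trajectory-heavy tests."""
    return SyntheticSystemSpec(
        group="low", n_residues=30, missing_residue_ids=(), guide="UAGC",
        target="GCUA", n_extra_ions=2, n_frames=50, seed=13,
    )


@pytest.fixture(scope="session")
def params():
    return toy_param_table()


@pytest.fixture()
def minimal_pdb(tmp_path):
    """Complete 2-residue, 5-atom protein fixture."""
    lines = [
        "ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N",
        "ATOM      2  CA  ALA A   1       2.000   2.000   3.000  1.00  0.00           C",
        "ATOM      3  C   ALA A   1       3.000   2.000   3.000  1.00  0.00           C",
        "ATOM      4  N   GLY A   2       4.000   2.000   3.000  1.00  0.00           N",
        "ATOM      5  CA  GLY A   2       5.000   2.000   3.000  1.00  0.00           C",
        "END",
    ]
    path = tmp_path / "minimal.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def make_point_topology(n: int, chain: str = "A", role: Role = Role.PROTEIN,
                        box: SimulationBox | None = None) -> ComplexTopology:
    """One CA atom per residue; handy for pure-geometry tests."""
    atoms = [
        AtomRecord(i + 1, "CA", "C", i + 1, "ALA", chain, role)
        for i in range(n)
    ]
    return ComplexTopology(atoms, box=box)


def make_trajectory(coords: np.ndarray, topology=None,
                    times=None) -> Trajectory:
    coords = np.asarray(coords, dtype=float)
    if topology is None:
        topology = make_point_topology(coords.shape[1])
    if times is None:
        times = np.arange(coords.shape[0], dtype=float)
    return Trajectory(topology, times, coords)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation via QR with determinant fix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
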