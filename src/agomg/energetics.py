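"""Duplex definition, per-base-pair nonbonded energies, regional averages.

The guide (miRNA) and target (mRNA) strands pair antiparallel: pair k joins
target position k (5'→3') with guide position L-k+1.  The 15-bp duplex is
partitioned into three regions indexed from the target 5' end — pairs 1–4
(target 5' / guide 3' terminus), 5–11 (central), 12–15 (target 3' / guide
5' terminus) — and a per-frame average pairing energy is reported per region
and for the whole duplex.

The pair interaction energy is a standard pairwise nonbonded sum over the
atoms of the two nucleotides,

    E = sum_ij  k_e q_i q_j / (eps_r r_ij)
             + eps_ij [ (R_ij/r_ij)^12 - 2 (R_ij/r_ij)^6 ],

with Lorentz-style combination eps_ij = sqrt(eps_i eps_j),
R_ij = Rmin_half_i + Rmin_half_j, Coulomb constant k_e = 332.0636
kcal·Å/(mol·e²), and distances min-imaged when the system is periodic.
Parameters come from a per-(residue, atom) table; a missing entry is an
error, never a silent zero.  By default only base atoms (heavy + base
hydrogens) enter the sum, since pairing is a base–base interaction; a
whole-nucleotide mode is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

from .geometry import min_image_displacement
from .structure_io import (
    ComplexTopology,
    NonbondedParamTable,
    Role,
    SimulationBox,
    Trajectory,
)

__all__ = [
    "COULOMB_CONSTANT",
    "RNA_BACKBONE_ATOMS",
    "WC_COMPLEMENT",
    "DuplexDefinition",
    "RegionPartition",
    "PairEnergyMatrix",
    "EnergyOptions",
    "build_duplex",
    "pair_interaction_energy",
    "duplex_energy_profile",
    "regional_average_energy",
    "ion_concentration_mM",
    "ions_for_concentration",
]

#: kcal·Å/(mol·e²)
COULOMB_CONSTANT = 332.0636

#: Ribose/phosphate atom names excluded in base-only mode.
RNA_BACKBONE_ATOMS = frozenset({
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'",
    "C3'", "O3'", "C2'", "O2'", "C1'",
})

WC_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

_RNA_ALPHABET = frozenset("ACGU")


@dataclass(frozen=True)
class DuplexDefinition:
    """Antiparallel guide/target pairing, indexed by target 5'→3' position."""

    guide: str  # 5'→3'
    target: str  # 5'→3'
    pairs: tuple[tuple[int, str, str], ...]  # (k, guide_nt, target_nt)

    @property
    def length(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class RegionPartition:
    """Contiguous, disjoint cover of pair indices 1..L by named regions."""

    boundaries: tuple[tuple[str, int, int], ...] = (
        ("Region1", 1, 4), ("Region2", 5, 11), ("Region3", 12, 15),
    )

    def __post_init__(self):
        prev_hi = 0
        for name, lo, hi in self.boundaries:
            if lo != prev_hi + 1 or hi < lo:
                raise ValueError(
                    f"regions must be contiguous and disjoint; bad {name} "
                    f"{lo}-{hi} after {prev_hi}"
                )
            prev_hi = hi

    @property
    def length(self) -> int:
        return self.boundaries[-1][2]

    def region_of(self, k: int) -> str:
        for name, lo, hi in self.boundaries:
            if lo <= k <= hi:
                return name
        raise ValueError(f"pair index {k} outside partition 1-{self.length}")

    def pairs_in(self, name: str) -> list[int]:
        for nm, lo, hi in self.boundaries:
            if nm == name:
                return list(range(lo, hi + 1))
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [nm for nm, _, _ in self.boundaries]


@dataclass
class PairEnergyMatrix:
    """Frames × base pairs interaction energies (kcal/mol)."""

    times_ps: np.ndarray  # (F,)
    energies: np.ndarray  # (F, L)

    def __post_init__(self):
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.shape[0] != self.times_ps.shape[0]:
            raise ValueError("times and energy rows differ")

    @property
    def n_pairs(self) -> int:
        return self.energies.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"pair_{k}": self.energies[:, k - 1]
                for k in range(1, self.n_pairs + 1)}
        return pd.DataFrame({"time_ps": self.times_ps, **cols})


@dataclass(frozen=True)
class EnergyOptions:
    """Atom inclusion and electrostatics options for the pairing energy."""

    base_only: bool = True
    relative_dielectric: float = 1.0
    periodic: bool = False
    box: SimulationBox | None = None

    def __post_init__(self):
        if self.relative_dielectric <= 0:
            raise ValueError("relative dielectric must be positive")
        if self.periodic and self.box is None:
            raise ValueError("periodic energies require a box")


# ---------------------------------------------------------------------------
# Duplex construction
# ---------------------------------------------------------------------------

def build_duplex(guide: str, target: str, strict_wc: bool = True
                 ) -> DuplexDefinition:
    """Pair a guide and target strand (both given 5'→3') antiparallel.

    Pair k joins target position k with guide position L-k+1.  In strict
    Watson–Crick mode every pair must be A–U or G–C; the first mismatch is
    reported by pair index.
    """
    guide = guide.upper().replace("T", "U")
    target = target.upper().replace("T", "U")
    if len(guide) != len(target):
        raise ValueError(
            f"strand lengths differ: guide {len(guide)}, target {len(target)}"
        )
    bad = (set(guide) | set(target)) - _RNA_ALPHABET
    if bad:
        raise ValueError(f"non-RNA characters in sequences: {sorted(bad)}")
    L = len(guide)
    pairs = []
    for k in range(1, L + 1):
        g_nt = guide[L - k]  # guide position L-k+1, 1-based
        t_nt = target[k - 1]
        if strict_wc and WC_COMPLEMENT[t_nt] != g_nt:
            raise ValueError(
                f"non-Watson-Crick pair at pair index {k}: "
                f"guide {g_nt} vs target {t_nt}"
            )
        pairs.append((k, g_nt, t_nt))
    return DuplexDefinition(guide, target, tuple(pairs))


# ---------------------------------------------------------------------------
# Pair interaction energy
# ---------------------------------------------------------------------------

def _nucleotide_atom_indices(topology: ComplexTopology, role: Role,
                             residue_id: int, base_only: bool) -> np.ndarray:
    mask = (topology.roles == role.value) & (topology.residue_ids == residue_id)
    if base_only:
        mask &= ~np.isin(topology.atom_names, list(RNA_BACKBONE_ATOMS))
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(
            f"no atoms for {role.value} residue {residue_id} "
            f"(base_only={base_only}); nucleotide unresolved?"
        )
    return idx


def _atomset_params(topology: ComplexTopology, idx: np.ndarray,
                    params: NonbondedParamTable):
    return params.arrays_for(topology.residue_names[idx],
                             topology.atom_names[idx])


def _nonbonded_sum(coords_a, coords_b, qa, qb, epsa, epsb, rmha, rmhb,
                   options: EnergyOptions) -> float:
    delta = coords_a[:, None, :] - coords_b[None, :, :]
    if options.periodic:
        delta = min_image_displacement(delta, options.box)
    r = np.sqrt(np.sum(delta ** 2, axis=2))
    if np.any(r == 0):
        raise ValueError("zero interatomic distance in energy evaluation")
    coul = COULOMB_CONSTANT * np.outer(qa, qb) / (
        options.relative_dielectric * r)
    eps_ij = np.sqrt(np.outer(epsa, epsb))
    r_ij = rmha[:, None] + rmhb[None, :]
    ratio6 = (r_ij / r) ** 6
    lj = eps_ij * (ratio6 ** 2 - 2.0 * ratio6)
    # exact summation keeps E(A, B) == E(B, A) to the last bit
    return math.fsum((coul + lj).ravel())


def pair_interaction_energy(
    frame: np.ndarray,
    topology: ComplexTopology,
    duplex: DuplexDefinition,
    pair_index: int,
    params: NonbondedParamTable,
    options: EnergyOptions = EnergyOptions(),
) -> float:
    """Nonbonded interaction energy (kcal/mol) of one guide–target pair."""
    L = duplex.length
    if not 1 <= pair_index <= L:
        raise ValueError(f"pair index {pair_index} outside 1-{L}")
    # guide chain residues numbered 1..L from its 5' end; pair k uses
    # guide residue L-k+1 and target residue k
    g_idx = _nucleotide_atom_indices(topology, Role.GUIDE_RNA,
                                     L - pair_index + 1, options.base_only)
    t_idx = _nucleotide_atom_indices(topology, Role.TARGET_RNA,
                                     pair_index, options.base_only)
    qa, epsa, rmha = _atomset_params(topology, g_idx, params)
    qb, epsb, rmhb = _atomset_params(topology, t_idx, params)
    frame = np.asarray(frame, dtype=float)
    return _nonbonded_sum(frame[g_idx], frame[t_idx], qa, qb, epsa, epsb,
                          rmha, rmhb, options)


def duplex_energy_profile(
    trajectory: Trajectory,
    duplex: DuplexDefinition,
    params: NonbondedParamTable,
    window_ps: tuple[float, float] | None = (7000.0, 10000.0),
    stride_ps: float | None = 5.0,
    options: EnergyOptions = EnergyOptions(),
) -> PairEnergyMatrix:
    """Per-pair energies over the sampled time window.

    Defaults sample every 5 ps over 7–10 ns (601 rows on a 1-ps trajectory
    of that span); pass ``window_ps=None`` to use every frame.
    """
    if window_ps is not None:
        traj = trajectory.window(window_ps[0], window_ps[1], stride_ps)
    else:
        traj = trajectory
    L = duplex.length
    energies = np.empty((traj.n_frames, L))
    for f in range(traj.n_frames):
        for k in range(1, L + 1):
            energies[f, k - 1] = pair_interaction_energy(
                traj.coords[f], traj.topology, duplex, k, params, options)
    return PairEnergyMatrix(traj.times_ps.copy(), energies)


def regional_average_energy(matrix: PairEnergyMatrix,
                            partition: RegionPartition = RegionPartition(),
                            ) -> pd.DataFrame:
    """Per-frame average pairing energy per region and over the whole duplex.

    Regional average = sum of the region's pair energies / region length.
    """
    if partition.length != matrix.n_pairs:
        raise ValueError(
            f"partition covers {partition.length} pairs, matrix has "
            f"{matrix.n_pairs}"
        )
    out = {"time_ps": matrix.times_ps}
    for name in partition.names:
        ks = np.array(partition.pairs_in(name)) - 1
        out[name] = matrix.energies[:, ks].mean(axis=1)
    out["whole"] = matrix.energies.mean(axis=1)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Box concentration arithmetic
# ---------------------------------------------------------------------------

def ion_concentration_mM(n_ions: int, box: SimulationBox) -> float:
    """Molar concentration (mM) of n ions in the box volume."""
    volume_L = box.volume_A3 * 1e-27
    return n_ions / (Avogadro * volume_L) * 1e3


def ions_for_concentration(concentration_mM: float, box: SimulationBox) -> int:
    """Ion count whose box concentration is nearest the requested one."""
    volume_L = box.volume_A3 * 1e-27
    return int(round(concentration_mM * 1e-3 * Avogadro * volume_L))
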