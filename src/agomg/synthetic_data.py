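"""Seeded synthetic Argonaute-duplex-ion systems with known ground truth.

The generator emulates the study design that the analysis stages expect —
a 682-residue protein with 18 unresolved residues (664 resolved Cα), a
15-bp perfectly complementary guide/target RNA duplex, two inner Mg²⁺ ions
buried near the PIWI range, up to 10 additional Mg²⁺ ions diffusing in a
152 Å cubic periodic box, and two conditions ("low" = no extra ions,
"high" = 10 extra ions) with four replicates each — without running any
molecular dynamics.

Protein geometry is coarse (Cα plus two dummy heavy atoms per residue on a
serpentine grid); the duplex is an ideal ladder whose Watson-Crick
donor-acceptor contacts sit 2.9 Å apart, giving G-C pairs three close
polar contacts and A-U pairs two.  Per-residue fluctuations are isotropic
Gaussians whose radial scale σ is the *target RMSF* (per-axis sd = σ/√3),
so a residue generated at σ recovers RMSF ≈ σ.  Energy observations for
the factorial analysis are drawn directly at the observation level as
Normal(μ_cell, σ_cell) per Region × Group cell.

Every generated dataset is accompanied by a :class:`GroundTruthRecord`
sufficient to score recovery by the downstream estimators.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import (
    AtomRecord,
    ComplexTopology,
    DomainMap,
    NonbondedParamTable,
    Role,
    SimulationBox,
    Trajectory,
)

__all__ = [
    "SyntheticSystemSpec",
    "GroundTruthRecord",
    "TABLE1_CELLS",
    "DEFAULT_GUIDE",
    "DEFAULT_TARGET",
    "DEFAULT_MISSING_RESIDUES",
    "default_sigma_profile",
    "generate_complex",
    "generate_trajectory",
    "generate_energy_table",
    "toy_param_table",
]

#: Guide (miRNA) strand 5'→3'.  Printed 3'→5' it reads GUCAGACUAUUCGAU.
DEFAULT_GUIDE = "UAGCUUAUCAGACUG"
#: Target (mRNA) strand 5'→3', perfectly complementary to the guide.
DEFAULT_TARGET = "CAGUCUGAUAAGCUA"

#: 18 author-numbered residues left unresolved by default (linker loops and
#: the C-terminal tail), so 682 declared - 18 missing = 664 resolved.
DEFAULT_MISSING_RESIDUES: tuple[int, ...] = tuple(
    list(range(101, 107)) + list(range(263, 269)) + [324, 325]
    + list(range(679, 683))
)

#: Default per-cell pairing-energy law (mean, sd) in kcal/mol for the
#: 3 regions x 2 groups design.
TABLE1_CELLS: dict[tuple[str, str], tuple[float, float]] = {
    ("Region1", "low"): (-3.346, 3.551),
    ("Region2", "low"): (-4.440, 2.945),
    ("Region3", "low"): (-4.979, 3.284),
    ("Region1", "high"): (-5.042, 4.733),
    ("Region2", "high"): (-6.313, 2.355),
    ("Region3", "high"): (-3.821, 3.671),
}

#: Ordered-state radial fluctuation targets (Å) by domain and condition.
#: The high-ion condition is uniformly stiffer, least so in PIWI.
_ORDERED_SIGMA = {
    "low": {"PAZ": 1.8, "MID": 1.2, "PIWI": 1.0, "other": 1.4},
    "high": {"PAZ": 1.2, "MID": 1.0, "PIWI": 0.95, "other": 1.1},
}
#: Disordered residues fluctuate well above the 3 Å entropy threshold.
_DISORDERED_SIGMA = 4.5
#: Fraction of resolved residues in the disordered state, per condition.
_DISORDER_FRACTION = {"low": 0.08, "high": 0.065}


@dataclass(frozen=True)
class SyntheticSystemSpec:
    """Parameters of one synthetic condition ("low" or "high" ion group)."""

    group: str = "low"
    n_residues: int = 682
    missing_residue_ids: tuple[int, ...] = DEFAULT_MISSING_RESIDUES
    guide: str = DEFAULT_GUIDE
    target: str = DEFAULT_TARGET
    n_extra_ions: int | None = None  # None -> 0 (low) / 10 (high)
    box_edge_A: float = 152.0
    n_frames: int = 400
    frame_interval_ps: float = 1.0
    sigma_profile: dict[int, float] | None = None  # resid -> target RMSF (Å)
    duplex_sigma_A: float = 0.5
    drift_per_frame_A: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ion_step_A: float = 2.0
    capture_radius_A: float = 10.0
    bind_probability: float = 0.05
    release_probability: float = 0.001
    n_replicates: int = 4
    n_timepoints: int = 601
    energy_cells: tuple[tuple[tuple[str, str], tuple[float, float]], ...] = (
        tuple(TABLE1_CELLS.items())
    )
    seed: int = 0

    def __post_init__(self):
        if self.group not in ("low", "high"):
            raise ValueError(f"group must be 'low' or 'high', got {self.group!r}")
        if len(self.guide) != len(self.target):
            raise ValueError("guide and target sequences must have equal length")
        if not (0 <= self.bind_probability <= 1
                and 0 <= self.release_probability <= 1):
            raise ValueError("kinetic probabilities must lie in [0, 1]")
        if self.sigma_profile is not None and any(
                s < 0 for s in self.sigma_profile.values()):
            raise ValueError("fluctuation sigmas must be >= 0")
        if self.n_timepoints <= 0 or self.n_replicates <= 0:
            raise ValueError("replicates and timepoints must be positive")

    @property
    def extra_ions(self) -> int:
        if self.n_extra_ions is not None:
            return self.n_extra_ions
        return 10 if self.group == "high" else 0

    def for_group(self, group: str) -> "SyntheticSystemSpec":
        return dataclasses.replace(self, group=group)

    def cells(self) -> dict[tuple[str, str], tuple[float, float]]:
        return dict(self.energy_cells)


@dataclass
class GroundTruthRecord:
    """What the generator actually used, for scoring estimator recovery."""

    group: str
    true_sigma: dict[int, float] = field(default_factory=dict)
    true_disorder_fraction: float = 0.0
    true_cells: dict[str, tuple[float, float]] = field(default_factory=dict)
    true_bound_whole: np.ndarray | None = None
    true_bound_duplex: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        blob = {
            "group": self.group,
            "true_sigma": {str(k): v for k, v in self.true_sigma.items()},
            "true_disorder_fraction": self.true_disorder_fraction,
            "true_cells": {k: list(v) for k, v in self.true_cells.items()},
            "true_bound_whole": (
                None if self.true_bound_whole is None
                else self.true_bound_whole.tolist()),
            "true_bound_duplex": (
                None if self.true_bound_duplex is None
                else self.true_bound_duplex.tolist()),
        }
        Path(path).write_text(json.dumps(blob, indent=1))


def _rng(spec: SyntheticSystemSpec, *stream: int) -> np.random.Generator:
    """Per-purpose RNG stream: global seed + fixed stream offsets."""
    group_code = 0 if spec.group == "low" else 1
    return np.random.default_rng([spec.seed, group_code, *stream])


def default_sigma_profile(spec: SyntheticSystemSpec,
                          domain_map: DomainMap | None = None,
                          ) -> tuple[dict[int, float], float]:
    """Per-resolved-residue target RMSF (Å) and the true disorder fraction.

    Ordered residues take the domain/condition value from the stiffness
    table; a fixed fraction is disordered (σ well above the 3 Å entropy
    threshold).  Disordered sets are nested across conditions — the "high"
    set is a subset of the "low" set — so paired low-minus-high RMSF
    differences are non-negative at every residue, as in a uniformly
    stiffened protein.
    """
    domain_map = domain_map or DomainMap()
    missing = set(spec.missing_residue_ids)
    resolved = [r for r in range(1, spec.n_residues + 1) if r not in missing]
    domains = domain_map.merged()

    def domain_of(rid: int) -> str:
        for name, resids in domains.items():
            if rid in resids:
                return name
        return "other"

    table = _ORDERED_SIGMA[spec.group]
    sigma = {rid: table[domain_of(rid)] for rid in resolved}

    n_low = int(round(_DISORDER_FRACTION["low"] * len(resolved)))
    n_here = int(round(_DISORDER_FRACTION[spec.group] * len(resolved)))
    # evenly-spaced picks over the resolved list; first n_here of the "low"
    # picks keeps the two conditions' disordered sets nested
    picks = [resolved[int(i * len(resolved) / n_low)] for i in range(n_low)]
    for rid in picks[:n_here]:
        sigma[rid] = _DISORDERED_SIGMA
    return sigma, n_here / len(resolved)


# ---------------------------------------------------------------------------
# Complex construction
# ---------------------------------------------------------------------------

#: Watson-Crick polar contact atoms per base: (atom, is_donor).
_BASE_CONTACTS = {
    "A": (("N1", False), ("N6", True)),
    "U": (("N3", True), ("O4", False)),
    "G": (("O6", False), ("N1", True), ("N2", True)),
    "C": (("N4", True), ("N3", False), ("O2", False)),
}
#: Contact pairing order across a WC pair, by base combination
#: (target base first).  A-U pairs make 2 contacts, G-C pairs 3.
_WC_CONTACTS = {
    ("A", "U"): (("N1", "N3"), ("N6", "O4")),
    ("U", "A"): (("N3", "N1"), ("O4", "N6")),
    ("G", "C"): (("O6", "N4"), ("N1", "N3"), ("N2", "O2")),
    ("C", "G"): (("N4", "O6"), ("N3", "N1"), ("O2", "N2")),
}


def toy_param_table() -> NonbondedParamTable:
    """Synthetic nonbonded parameters for the coarse nucleotide model.

    Donor atoms carry positive and acceptors negative partial charges,
    balanced so every base is net neutral (pair energies then decay like
    dipole-dipole interactions at separation); each aligned donor-acceptor
    contact of the ladder contributes an attractive Coulomb term, so G-C
    pairs (three contacts) bind more strongly than A-U (two).  Backbone P
    is -1.0 e (phosphate, excluded in base-only mode) and C1' neutral; LJ
    parameters are uniform and small so sterics do not dominate the wells.
    """
    charges = {
        ("A", "N6"): 0.4, ("A", "N1"): -0.4,
        ("U", "N3"): 0.4, ("U", "O4"): -0.4,
        ("G", "N1"): 0.4, ("G", "N2"): 0.4, ("G", "O6"): -0.8,
        ("C", "N4"): 0.8, ("C", "N3"): -0.4, ("C", "O2"): -0.4,
    }
    rows = []
    for base, contacts in _BASE_CONTACTS.items():
        for atom, _ in contacts:
            rows.append((base, atom, charges[(base, atom)], 0.05, 1.6))
        rows.append((base, "C1'", 0.0, 0.05, 2.0))
        rows.append((base, "P", -1.0, 0.05, 2.1))
    frame = pd.DataFrame(rows, columns=NonbondedParamTable.COLUMNS)
    return NonbondedParamTable(frame)


def _protein_records_and_coords(spec: SyntheticSystemSpec, center: np.ndarray
                                ) -> tuple[list[AtomRecord], list[np.ndarray]]:
    """Cα + 2 dummy heavy atoms per resolved residue on a serpentine grid.

    Consecutive grid sites are 5 Å apart and each site is visited at most
    once, so the coarse backbone is self-avoiding by construction; missing
    residues leave their grid sites empty.
    """
    spacing = 5.0
    side = int(np.ceil(spec.n_residues ** (1 / 3)))
    missing = set(spec.missing_residue_ids)
    records, coords = [], []
    atom_id = 1
    offsets = {"CA": np.zeros(3), "CB": np.array([1.2, 1.0, 0.4]),
               "O": np.array([-1.0, 0.8, -0.6])}
    origin = center - spacing * (side - 1) / 2.0
    for rid in range(1, spec.n_residues + 1):
        i = rid - 1
        iz, rem = divmod(i, side * side)
        iy, ix = divmod(rem, side)
        # serpentine: alternate direction per row/plane to keep neighbors
        # 5 Å apart
        if iy % 2 == 1:
            ix = side - 1 - ix
        if iz % 2 == 1:
            iy = side - 1 - iy
        if rid in missing:
            continue
        base = origin + spacing * np.array([ix, iy, iz], dtype=float)
        for name, off in offsets.items():
            records.append(AtomRecord(atom_id, name, "C" if name != "O" else "O",
                                      rid, "ALA", "A", Role.PROTEIN))
            coords.append(base + off)
            atom_id += 1
    return records, coords


def _duplex_records_and_coords(spec: SyntheticSystemSpec, start_id: int,
                               anchor: np.ndarray
                               ) -> tuple[list[AtomRecord], list[np.ndarray]]:
    """Ideal ladder: pair k at z = 3.4k, donor-acceptor contacts 2.9 Å apart."""
    from .energetics import build_duplex  # local import avoids cycle

    duplex = build_duplex(spec.guide, spec.target, strict_wc=False)
    records, coords = [], []
    atom_id = start_id
    L = duplex.length
    rise = 3.4
    for k, g_nt, t_nt in duplex.pairs:
        z = anchor[2] + rise * k
        contacts = _WC_CONTACTS.get((t_nt, g_nt))
        placed_t: dict[str, np.ndarray] = {}
        placed_g: dict[str, np.ndarray] = {}
        if contacts is not None:
            for j, (t_atom, g_atom) in enumerate(contacts):
                y = anchor[1] + 3.0 * j
                placed_t[t_atom] = np.array([anchor[0], y, z])
                placed_g[g_atom] = np.array([anchor[0] + 2.9, y, z])
        # non-contact mismatched bases: spread atoms without alignment
        for atom, _ in _BASE_CONTACTS[t_nt]:
            placed_t.setdefault(atom, np.array(
                [anchor[0] - 1.0, anchor[1] + 2.0 * len(placed_t), z]))
        for atom, _ in _BASE_CONTACTS[g_nt]:
            placed_g.setdefault(atom, np.array(
                [anchor[0] + 3.9, anchor[1] + 2.0 * len(placed_g), z]))
        placed_t["C1'"] = np.array([anchor[0] - 3.0, anchor[1] - 3.0, z])
        placed_t["P"] = np.array([anchor[0] - 5.0, anchor[1] - 5.0, z])
        placed_g["C1'"] = np.array([anchor[0] + 5.9, anchor[1] - 3.0, z])
        placed_g["P"] = np.array([anchor[0] + 7.9, anchor[1] - 5.0, z])
        # target chain T residue k; guide chain G residue L-k+1
        for atom, pos in placed_t.items():
            records.append(AtomRecord(atom_id, atom, atom[0], k, t_nt, "T",
                                      Role.TARGET_RNA))
            coords.append(pos)
            atom_id += 1
        for atom, pos in placed_g.items():
            records.append(AtomRecord(atom_id, atom, atom[0], L - k + 1,
                                      g_nt, "G", Role.GUIDE_RNA))
            coords.append(pos)
            atom_id += 1
    return records, coords


def generate_complex(spec: SyntheticSystemSpec
                     ) -> tuple[ComplexTopology, np.ndarray]:
    """Build the coarse complex: protein, duplex ladder, inner + extra ions.

    Deterministic under the spec's seed; the two inner ions sit within 5 Å
    of PIWI-range Cα atoms and the extra ions start uniformly in the box.
    """
    box = SimulationBox((spec.box_edge_A,) * 3)
    center = np.full(3, spec.box_edge_A / 2.0)
    records, coords = _protein_records_and_coords(spec, center)

    duplex_anchor = center + np.array([30.0, 0.0, -0.5 * 3.4 * len(spec.guide)])
    next_id = records[-1].atom_id + 1
    drec, dcoords = _duplex_records_and_coords(spec, next_id, duplex_anchor)
    records += drec
    coords += dcoords

    # inner ions: within 5 A of the first two resolved PIWI-range Calphas
    piwi_ca = [
        (r, c) for r, c in zip(records, coords)
        if r.role is Role.PROTEIN and r.atom_name == "CA"
        and 463 <= r.residue_id <= 678
    ]
    next_id = records[-1].atom_id + 1
    ion_resid = 1
    for _, ca in piwi_ca[:2]:
        records.append(AtomRecord(next_id, "MG", "MG", ion_resid, "MG", "M",
                                  Role.ION))
        coords.append(ca + np.array([0.0, 0.0, 3.0]))
        next_id += 1
        ion_resid += 1

    rng = _rng(spec, 1)  # stream 1: ion placement
    for _ in range(spec.extra_ions):
        records.append(AtomRecord(next_id, "MG", "MG", ion_resid, "MG", "M",
                                  Role.ION))
        coords.append(rng.uniform(0.0, spec.box_edge_A, size=3))
        next_id += 1
        ion_resid += 1

    topo = ComplexTopology(
        records,
        declared_residue_ranges={"A": (1, spec.n_residues)},
        box=box,
    )
    return topo, np.array(coords)


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------

def generate_trajectory(spec: SyntheticSystemSpec, replicate: int = 0
                        ) -> tuple[Trajectory, GroundTruthRecord]:
    """Fluctuating frames around the ideal complex with ion kinetics.

    Residue i at frame t is its mean position plus an isotropic Gaussian
    of radial scale σ_i (per-axis sd σ_i/√3, one displacement per residue
    applied to all its atoms, so the Cα RMSF recovers σ_i).  Extra ions
    perform periodic random walks; a free ion within the capture radius of
    the complex binds with the per-frame bind probability, sticks 3 Å from
    its anchor atom, and releases with the release probability.  An
    optional per-frame rigid drift exercises trajectory alignment.
    """
    topo, base = generate_complex(spec)
    if spec.sigma_profile is not None:
        sigma = dict(spec.sigma_profile)
        resolved = topo.n_resolved("A")
        n_dis = sum(1 for s in sigma.values() if s >= 3.0)
        disorder_fraction = n_dis / max(resolved, 1)
    else:
        sigma, disorder_fraction = default_sigma_profile(spec)

    rng = _rng(spec, 2, replicate)  # stream 2: thermal noise + kinetics

    prot_mask = topo.roles == Role.PROTEIN.value
    rna_mask = np.isin(topo.roles,
                       [Role.GUIDE_RNA.value, Role.TARGET_RNA.value])
    ion_idx = np.flatnonzero(topo.roles == Role.ION.value)
    complex_idx = np.flatnonzero(prot_mask | rna_mask)
    duplex_idx = np.flatnonzero(rna_mask)
    duplex_idx_set = set(duplex_idx.tolist())
    inner_idx = ion_idx[:2]
    extra_idx = ion_idx[2:]

    # per-residue atom index lists for the protein
    res_atoms: dict[int, np.ndarray] = {}
    for rid in np.unique(topo.residue_ids[prot_mask]):
        res_atoms[int(rid)] = np.flatnonzero(
            prot_mask & (topo.residue_ids == rid))

    # per-nucleotide groups move together too
    nt_groups = []
    for chain in ("G", "T"):
        cmask = topo.chain_ids == chain
        for rid in np.unique(topo.residue_ids[cmask]):
            nt_groups.append(np.flatnonzero(cmask & (topo.residue_ids == rid)))

    edge = spec.box_edge_A
    n_extra = len(extra_idx)
    ion_pos = base[extra_idx].copy()
    bound_anchor = np.full(n_extra, -1, dtype=int)  # -1 = free
    frames = np.empty((spec.n_frames, topo.n_atoms, 3))
    bound_whole = np.empty(spec.n_frames, dtype=int)
    bound_duplex = np.empty(spec.n_frames, dtype=int)
    drift = np.asarray(spec.drift_per_frame_A, dtype=float)

    for f in range(spec.n_frames):
        frame = base.copy()
        # thermal fluctuation, one isotropic draw per residue/nucleotide
        for rid, idx in res_atoms.items():
            s = sigma.get(rid, 0.0) / np.sqrt(3.0)
            if s > 0:
                frame[idx] += rng.normal(0.0, s, size=3)
        if spec.duplex_sigma_A > 0:
            s = spec.duplex_sigma_A / np.sqrt(3.0)
            for idx in nt_groups:
                frame[idx] += rng.normal(0.0, s, size=3)
        # inner ions jitter in place, staying bound
        frame[inner_idx] += rng.normal(0.0, 0.2, size=(len(inner_idx), 3))

        complex_pos = frame[complex_idx]
        for i in range(n_extra):
            if bound_anchor[i] >= 0:
                if rng.random() < spec.release_probability:
                    bound_anchor[i] = -1  # released; walks freely below
                else:
                    frame[extra_idx[i]] = frame[bound_anchor[i]] + np.array(
                        [0.0, 0.0, 3.0])
                    ion_pos[i] = frame[extra_idx[i]]
                    continue
            # free: periodic random walk
            step = rng.normal(0.0, spec.ion_step_A, size=3)
            ion_pos[i] = np.mod(ion_pos[i] + step, edge)
            delta = complex_pos - ion_pos[i]
            delta -= edge * np.round(delta / edge)
            d = np.sqrt(np.sum(delta ** 2, axis=1))
            nearest = int(np.argmin(d))
            if (d[nearest] < spec.capture_radius_A
                    and rng.random() < spec.bind_probability):
                bound_anchor[i] = int(complex_idx[nearest])
                frame[extra_idx[i]] = frame[bound_anchor[i]] + np.array(
                    [0.0, 0.0, 3.0])
                ion_pos[i] = frame[extra_idx[i]]
            else:
                frame[extra_idx[i]] = ion_pos[i]

        n_bound_extra = int(np.sum(bound_anchor >= 0))
        bound_whole[f] = len(inner_idx) + n_bound_extra
        bound_duplex[f] = int(np.sum(
            [a in duplex_idx_set for a in bound_anchor if a >= 0]))
        frame += drift * f
        frames[f] = frame

    times = spec.frame_interval_ps * np.arange(spec.n_frames)
    traj = Trajectory(topo, times, frames)
    truth = GroundTruthRecord(
        group=spec.group,
        true_sigma=sigma,
        true_disorder_fraction=disorder_fraction,
        true_bound_whole=bound_whole,
        true_bound_duplex=bound_duplex,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# Energy observation tables
# ---------------------------------------------------------------------------

def generate_energy_table(spec: SyntheticSystemSpec, groups=("low", "high")
                          ) -> tuple[pd.DataFrame, GroundTruthRecord]:
    """Long-format (energy, region, group, replicate, time_ps) observations.

    Each Region × Group cell receives n_replicates × n_timepoints i.i.d.
    Normal draws at its (mean, sd); the default parameterization is the
    reported regional energy profile with 4 × 601 observations per cell
    (5-ps sampling over the 7-10 ns window).  Each (group, replicate)
    pair draws from its own seeded stream.
    """
    cells = spec.cells()
    regions = sorted({r for r, _ in cells})
    times = 7000.0 + 5.0 * np.arange(spec.n_timepoints)
    rows = []
    for group in groups:
        for rep in range(spec.n_replicates):
            group_code = 0 if group == "low" else 1
            rng = np.random.default_rng([spec.seed, 3, group_code, rep])
            for region in regions:
                mu, sd = cells[(region, group)]
                if sd < 0:
                    raise ValueError(f"negative sd for cell ({region}, {group})")
                draws = rng.normal(mu, sd, size=spec.n_timepoints)
                for t, e in zip(times, draws):
                    rows.append((e, region, group, rep, t))
    table = pd.DataFrame(rows, columns=["energy", "region", "group",
                                        "replicate", "time_ps"])
    truth = GroundTruthRecord(
        group="both",
        true_cells={f"{r}:{g}": cells[(r, g)] for g in groups for r in regions},
    )
    return table, truth
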