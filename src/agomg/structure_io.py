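"""Structure, trajectory and table I/O with missing-residue bookkeeping.

The topology model tracks which author-numbered residues of each chain are
resolved in the coordinate file and which are declared but absent, so that
per-residue analyses (RMSF, entropy, domain selections) operate on exactly
the resolved residues and never silently repair gaps.

PDB reading/writing is delegated to biotite; this module adds the
role-annotated topology, gap inference, selections, and the TSV dialects
used for parameter tables and fixture trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

logger = logging.getLogger("agomg")

__all__ = [
    "Role",
    "AtomRecord",
    "SimulationBox",
    "DomainMap",
    "ComplexTopology",
    "Trajectory",
    "NonbondedParamTable",
    "PDBFormatError",
    "TopologyError",
    "SelectionError",
    "ParameterLookupError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_param_table",
    "write_param_table",
    "select_atoms",
]


class PDBFormatError(ValueError):
    """A structure/trajectory file could not be parsed."""


class TopologyError(ValueError):
    """Topology invariants violated (duplicate ids, residue accounting...)."""


class SelectionError(ValueError):
    """An atom selection referenced entities absent from the topology."""


class ParameterLookupError(KeyError):
    """A nonbonded parameter lookup failed; never treated as a silent zero."""


class Role(str, Enum):
    PROTEIN = "protein"
    GUIDE_RNA = "guide_rna"
    TARGET_RNA = "target_rna"
    ION = "ion"
    OTHER = "other"


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the complex, in author numbering."""

    atom_id: int
    atom_name: str
    element: str
    residue_id: int
    residue_name: str
    chain_id: str
    role: Role

    def __post_init__(self):
        if self.residue_id <= 0:
            raise TopologyError(
                f"residue_id must be positive, got {self.residue_id} "
                f"(atom {self.atom_id})"
            )


@dataclass(frozen=True)
class SimulationBox:
    """Cubic periodic box; minimum-image arithmetic only supports cubes."""

    edge_lengths: tuple[float, float, float]
    periodic: bool = True

    def __post_init__(self):
        if any(e <= 0 for e in self.edge_lengths):
            raise ValueError(f"box edges must be positive: {self.edge_lengths}")
        if self.periodic and len(set(self.edge_lengths)) != 1:
            raise ValueError(
                "only cubic periodic boxes are supported, got edges "
                f"{self.edge_lengths}"
            )

    @property
    def edge(self) -> float:
        return self.edge_lengths[0]

    @property
    def volume_A3(self) -> float:
        a, b, c = self.edge_lengths
        return a * b * c


#: Default domain partition of the Argonaute protein, in author residue
#: numbering.  PAZ is split into two subranges in sequence.
DEFAULT_DOMAINS: dict[str, tuple[tuple[int, int], ...]] = {
    "PAZ_sub1": ((20, 100),),
    "PAZ_sub2": ((170, 260),),
    "MID": ((326, 462),),
    "PIWI": ((463, 678),),
}


@dataclass(frozen=True)
class DomainMap:
    """Named residue ranges on the protein chain (inclusive bounds)."""

    ranges: Mapping[str, tuple[tuple[int, int], ...]] = field(
        default_factory=lambda: dict(DEFAULT_DOMAINS)
    )

    def __post_init__(self):
        flat = []
        for name, rngs in self.ranges.items():
            for lo, hi in rngs:
                if lo > hi or lo <= 0:
                    raise ValueError(f"bad range for domain {name}: {lo}-{hi}")
                flat.append((lo, hi, name))
        flat.sort()
        for (lo1, hi1, n1), (lo2, hi2, n2) in zip(flat, flat[1:]):
            if lo2 <= hi1:
                raise ValueError(
                    f"overlapping domain ranges: {n1} {lo1}-{hi1} vs {n2} {lo2}-{hi2}"
                )

    def residues(self, name: str) -> set[int]:
        out: set[int] = set()
        for lo, hi in self.ranges[name]:
            out.update(range(lo, hi + 1))
        return out

    def merged(self) -> dict[str, set[int]]:
        """Domain → residue-id sets, with PAZ subranges merged into 'PAZ'."""
        merged: dict[str, set[int]] = {}
        for name in self.ranges:
            key = "PAZ" if name.startswith("PAZ") else name
            merged.setdefault(key, set()).update(self.residues(name))
        return merged


class ComplexTopology:
    """Atoms of the complex plus per-chain residue accounting.

    Parameters
    ----------
    atoms
        Atom records in file order.
    declared_residue_ranges
        chain_id -> (first, last) author residue numbers declared for the
        chain.  Residues in the range but absent from `atoms` are recorded
        as missing.  Chains not listed are taken as fully resolved.
    box, domain_map
        Periodic box and protein domain partition.
    """

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        declared_residue_ranges: Mapping[str, tuple[int, int]] | None = None,
        box: SimulationBox | None = None,
        domain_map: DomainMap | None = None,
    ):
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        self.box = box
        self.domain_map = domain_map or DomainMap()

        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise TopologyError(f"duplicate atom_id(s): {sorted(dupes)[:5]}")

        observed: dict[str, set[int]] = {}
        for a in self.atoms:
            observed.setdefault(a.chain_id, set()).add(a.residue_id)
        self._observed_residues = observed

        self.declared_residue_ranges: dict[str, tuple[int, int]] = {}
        missing: set[tuple[str, int]] = set()
        for chain, obs in observed.items():
            if declared_residue_ranges and chain in declared_residue_ranges:
                first, last = declared_residue_ranges[chain]
            else:
                first, last = min(obs), max(obs)
            self.declared_residue_ranges[chain] = (first, last)
            outside = obs - set(range(first, last + 1))
            if outside:
                raise TopologyError(
                    f"chain {chain}: observed residues {sorted(outside)[:5]} "
                    f"outside declared range {first}-{last}"
                )
            for rid in range(first, last + 1):
                if rid not in obs:
                    missing.add((chain, rid))
        self.missing_residues: frozenset[tuple[str, int]] = frozenset(missing)

        # accounting invariant: resolved + missing == declared, per chain
        for chain, (first, last) in self.declared_residue_ranges.items():
            declared = last - first + 1
            resolved = len(observed[chain])
            n_missing = sum(1 for c, _ in missing if c == chain)
            if resolved + n_missing != declared:
                raise TopologyError(
                    f"chain {chain}: resolved ({resolved}) + missing "
                    f"({n_missing}) != declared ({declared})"
                )

        # ions must be single-atom residues
        ion_res: dict[tuple[str, int], int] = {}
        for a in self.atoms:
            if a.role is Role.ION:
                key = (a.chain_id, a.residue_id)
                ion_res[key] = ion_res.get(key, 0) + 1
        bad = [k for k, n in ion_res.items() if n != 1]
        if bad:
            raise TopologyError(f"ion residues with != 1 atom: {bad[:5]}")

    # --- vectorized views ------------------------------------------------
    @cached_property
    def atom_ids(self) -> np.ndarray:
        return np.array([a.atom_id for a in self.atoms], dtype=int)

    @cached_property
    def atom_names(self) -> np.ndarray:
        return np.array([a.atom_name for a in self.atoms])

    @cached_property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    @cached_property
    def residue_ids(self) -> np.ndarray:
        return np.array([a.residue_id for a in self.atoms], dtype=int)

    @cached_property
    def residue_names(self) -> np.ndarray:
        return np.array([a.residue_name for a in self.atoms])

    @cached_property
    def chain_ids(self) -> np.ndarray:
        return np.array([a.chain_id for a in self.atoms])

    @cached_property
    def roles(self) -> np.ndarray:
        return np.array([a.role.value for a in self.atoms])

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def resolved_residues(self, chain_id: str) -> list[int]:
        return sorted(self._observed_residues.get(chain_id, set()))

    def n_resolved(self, chain_id: str) -> int:
        return len(self._observed_residues.get(chain_id, set()))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ComplexTopology)
            and self.atoms == other.atoms
            and self.declared_residue_ranges == other.declared_residue_ranges
            and self.missing_residues == other.missing_residues
            and self.box == other.box
        )


@dataclass
class Trajectory:
    """Time-stamped coordinate frames over the resolved atoms of a topology."""

    topology: ComplexTopology
    times_ps: np.ndarray  # (F,)
    coords: np.ndarray  # (F, N, 3) in Å

    def __post_init__(self):
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (F, N, 3), got {self.coords.shape}")
        if self.coords.shape[0] != self.times_ps.shape[0]:
            raise ValueError("frame count of times and coords differ")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"trajectory has {self.coords.shape[1]} atoms per frame but "
                f"topology has {self.topology.n_atoms}"
            )
        if np.any(np.diff(self.times_ps) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def window(self, t_start: float, t_end: float, stride_ps: float | None = None
               ) -> "Trajectory":
        """Frames with t_start <= t <= t_end, optionally on a stride grid."""
        mask = (self.times_ps >= t_start) & (self.times_ps <= t_end)
        if stride_ps is not None:
            on_grid = np.isclose(
                np.mod(self.times_ps - t_start, stride_ps), 0.0, atol=1e-9
            ) | np.isclose(
                np.mod(self.times_ps - t_start, stride_ps), stride_ps, atol=1e-9
            )
            mask &= on_grid
        if not mask.any():
            raise ValueError(
                f"empty time window [{t_start}, {t_end}] ps (stride {stride_ps})"
            )
        return Trajectory(self.topology, self.times_ps[mask], self.coords[mask])


class NonbondedParamTable:
    """Per (residue_name, atom_name) partial charge and LJ parameters.

    Lookup failure raises :class:`ParameterLookupError`; energies are never
    computed with silently-zeroed parameters.
    """

    COLUMNS = ("residue_name", "atom_name", "charge_e",
               "lj_epsilon_kcal_mol", "lj_rmin_half_A")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"parameter table missing columns: {sorted(missing)}")
        if (frame["lj_epsilon_kcal_mol"] < 0).any():
            raise ValueError("lj_epsilon must be >= 0")
        if (frame["lj_rmin_half_A"] <= 0).any():
            raise ValueError("lj_rmin_half must be > 0")
        self.frame = frame.reset_index(drop=True)
        self._index: dict[tuple[str, str], tuple[float, float, float]] = {
            (r.residue_name, r.atom_name): (
                float(r.charge_e),
                float(r.lj_epsilon_kcal_mol),
                float(r.lj_rmin_half_A),
            )
            for r in frame.itertuples(index=False)
        }

    def lookup(self, residue_name: str, atom_name: str
               ) -> tuple[float, float, float]:
        try:
            return self._index[(residue_name, atom_name)]
        except KeyError:
            raise ParameterLookupError(
                f"no nonbonded parameters for atom {atom_name!r} of residue "
                f"{residue_name!r}"
            ) from None

    def arrays_for(self, residue_names: np.ndarray, atom_names: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized lookup; raises on the first missing entry."""
        q = np.empty(len(atom_names))
        eps = np.empty(len(atom_names))
        rmh = np.empty(len(atom_names))
        for i, (rn, an) in enumerate(zip(residue_names, atom_names)):
            q[i], eps[i], rmh[i] = self.lookup(rn, an)
        return q, eps, rmh


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _check_coordinate_lines(path: Path) -> None:
    """Pre-validate ATOM/HETATM coordinate columns to report line numbers."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        raise PDBFormatError(
                            f"{path}, line {lineno}: non-numeric coordinate "
                            f"field {line[lo:hi].strip()!r}"
                        ) from None


def _atom_array_to_records(
    arr: struc.AtomArray, role_assignment: Mapping[str, Role | str]
) -> list[AtomRecord]:
    roles = {c: Role(r) for c, r in role_assignment.items()}
    unknown = set(np.unique(arr.chain_id)) - set(roles)
    if unknown:
        raise SelectionError(
            f"role_assignment does not cover chain(s) {sorted(unknown)}"
        )
    records = []
    for i in range(arr.array_length()):
        records.append(
            AtomRecord(
                atom_id=int(arr.atom_id[i]) if "atom_id" in arr.get_annotation_categories() else i + 1,
                atom_name=str(arr.atom_name[i]),
                element=str(arr.element[i]),
                residue_id=int(arr.res_id[i]),
                residue_name=str(arr.res_name[i]),
                chain_id=str(arr.chain_id[i]),
                role=roles[str(arr.chain_id[i])],
            )
        )
    return records


def read_structure(
    path: str | Path,
    role_assignment: Mapping[str, Role | str],
    declared_residue_ranges: Mapping[str, tuple[int, int]] | None = None,
    box: SimulationBox | None = None,
    domain_map: DomainMap | None = None,
) -> tuple[ComplexTopology, np.ndarray]:
    """Read a single-model PDB into a topology and its coordinate frame.

    Alternate locations keep the highest occupancy (first on ties); missing
    residues are inferred from gaps between the declared residue ranges and
    the observed author numbering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_coordinate_lines(path)
    try:
        pfile = pdb.PDBFile.read(str(path))
        arr = pfile.get_structure(model=1, altloc="occupancy",
                                  extra_fields=["atom_id"])
    except PDBFormatError:
        raise
    except Exception as exc:  # biotite raises assorted parse errors
        raise PDBFormatError(f"cannot parse {path}: {exc}") from exc

    if box is None:
        pdb_box = arr.box
        if pdb_box is not None:
            edges = tuple(float(x) for x in np.diag(np.asarray(pdb_box)))
            if all(e > 0 for e in edges):
                box = SimulationBox(edges, periodic=True)

    records = _atom_array_to_records(arr, role_assignment)
    topo = ComplexTopology(records, declared_residue_ranges, box, domain_map)
    return topo, np.asarray(arr.coord, dtype=float)


def _topology_to_atom_array(topology: ComplexTopology, coords: np.ndarray
                            ) -> struc.AtomArray:
    n = topology.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = topology.chain_ids
    arr.res_id = topology.residue_ids
    arr.res_name = topology.residue_names
    arr.atom_name = topology.atom_names
    arr.element = topology.elements
    arr.set_annotation("atom_id", topology.atom_ids)
    arr.hetero = np.array(
        [a.role in (Role.ION, Role.OTHER) for a in topology.atoms]
    )
    if topology.box is not None:
        arr.box = np.diag(topology.box.edge_lengths).astype(np.float32)
    return arr


def write_structure(path: str | Path, topology: ComplexTopology,
                    coords: np.ndarray) -> None:
    arr = _topology_to_atom_array(topology, coords)
    pfile = pdb.PDBFile()
    pfile.set_structure(arr)
    pfile.write(str(path))


def write_trajectory(path: str | Path, trajectory: Trajectory) -> None:
    """Write a trajectory as multi-model PDB (.pdb) or long-form TSV (.tsv)."""
    path = Path(path)
    if path.suffix.lower() in (".tsv", ".txt"):
        topo = trajectory.topology
        frames = []
        for t, frame in zip(trajectory.times_ps, trajectory.coords):
            frames.append(pd.DataFrame({
                "time_ps": t,
                "atom_id": topo.atom_ids,
                "x": frame[:, 0], "y": frame[:, 1], "z": frame[:, 2],
            }))
        pd.concat(frames).to_csv(path, sep="\t", index=False,
                                 float_format="%.3f")
        return
    n_frames = trajectory.n_frames
    stack = struc.AtomArrayStack(n_frames, trajectory.topology.n_atoms)
    template = _topology_to_atom_array(trajectory.topology,
                                       trajectory.coords[0])
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = trajectory.coords.astype(np.float32)
    if trajectory.topology.box is not None:
        stack.box = np.repeat(
            np.diag(trajectory.topology.box.edge_lengths)[None, :, :],
            n_frames, axis=0,
        ).astype(np.float32)
    pfile = pdb.PDBFile()
    pfile.set_structure(stack)
    pfile.write(str(path))


def read_trajectory(
    topology: ComplexTopology,
    path: str | Path,
    time_start_ps: float = 0.0,
    time_stride_ps: float = 1.0,
) -> Trajectory:
    """Read a multi-model PDB or TSV coordinate table against a topology.

    Frame times come from the file (TSV) or from ``time_start_ps +
    i * time_stride_ps`` over MODEL index i (PDB carries no time stamps).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tsv", ".txt"):
        table = pd.read_csv(path, sep="\t")
        need = {"time_ps", "atom_id", "x", "y", "z"}
        if not need.issubset(table.columns):
            raise PDBFormatError(
                f"{path}: TSV trajectory must have columns {sorted(need)}"
            )
        times = np.array(sorted(table["time_ps"].unique()))
        frames = []
        order = {aid: i for i, aid in enumerate(topology.atom_ids)}
        for fidx, t in enumerate(times):
            sub = table[table["time_ps"] == t]
            if len(sub) != topology.n_atoms:
                raise PDBFormatError(
                    f"frame {fidx}: expected {topology.n_atoms} atoms, "
                    f"got {len(sub)}"
                )
            frame = np.empty((topology.n_atoms, 3))
            for row in sub.itertuples(index=False):
                frame[order[row.atom_id]] = (row.x, row.y, row.z)
            frames.append(frame)
        return Trajectory(topology, times, np.array(frames))

    _check_coordinate_lines(path)
    try:
        pfile = pdb.PDBFile.read(str(path))
        stack = pfile.get_structure(model=None, altloc="occupancy")
    except PDBFormatError:
        raise
    except Exception as exc:
        # count atoms per model by hand to point at the offending frame
        _diagnose_model_counts(path, topology.n_atoms)
        raise PDBFormatError(f"cannot parse {path}: {exc}") from exc
    coords = np.asarray(stack.coord, dtype=float)
    if coords.shape[1] != topology.n_atoms:
        _diagnose_model_counts(path, topology.n_atoms)
        raise PDBFormatError(
            f"{path}: frames have {coords.shape[1]} atoms, topology has "
            f"{topology.n_atoms}"
        )
    times = time_start_ps + time_stride_ps * np.arange(coords.shape[0])
    return Trajectory(topology, times, coords)


def _diagnose_model_counts(path: Path, expected: int) -> None:
    counts: list[int] = []
    current = 0
    in_model = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                in_model, current = True, 0
            elif line.startswith("ENDMDL"):
                counts.append(current)
                in_model = False
            elif line.startswith(("ATOM", "HETATM")) and in_model:
                current += 1
    for i, c in enumerate(counts):
        if c != expected:
            raise PDBFormatError(
                f"{path}: frame {i} has {c} atoms, expected {expected}"
            )


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

def read_param_table(path: str | Path) -> NonbondedParamTable:
    frame = pd.read_csv(path, sep="\t")
    return NonbondedParamTable(frame)


def write_param_table(path: str | Path, table: NonbondedParamTable) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def select_atoms(
    topology: ComplexTopology,
    chains: Iterable[str] | None = None,
    residue_ranges: Iterable[tuple[int, int]] | None = None,
    atom_names: Iterable[str] | None = None,
    roles: Iterable[Role | str] | None = None,
    heavy_only: bool = True,
) -> np.ndarray:
    """Indices (file order) of atoms matching all given criteria.

    ``heavy_only`` drops hydrogens (element H), matching the convention of
    superposing "all atoms except hydrogen".  An empty result is legal but
    logged as a warning, since it usually indicates a selection typo.
    """
    mask = np.ones(topology.n_atoms, dtype=bool)
    if chains is not None:
        chains = list(chains)
        known = set(topology.chains())
        unknown = set(chains) - known
        if unknown:
            raise SelectionError(
                f"unknown chain(s) {sorted(unknown)}; topology has "
                f"{sorted(known)}"
            )
        mask &= np.isin(topology.chain_ids, chains)
    if roles is not None:
        role_vals = [Role(r).value for r in roles]
        mask &= np.isin(topology.roles, role_vals)
    if residue_ranges is not None:
        rmask = np.zeros(topology.n_atoms, dtype=bool)
        rids = topology.residue_ids
        for lo, hi in residue_ranges:
            rmask |= (rids >= lo) & (rids <= hi)
        mask &= rmask
    if atom_names is not None:
        mask &= np.isin(topology.atom_names, list(atom_names))
    if heavy_only:
        mask &= topology.elements != "H"
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        logger.warning("select_atoms: empty selection (chains=%s, ranges=%s, "
                       "names=%s, roles=%s)", chains, residue_ranges,
                       atom_names, roles)
    return idx
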