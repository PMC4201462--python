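"""Superposition, fluctuation profiles, periodic distances and ion contacts.

Rigid-body superposition uses the Kabsch algorithm (SVD of the covariance
matrix with reflection suppression), the standard least-squares fit between
paired point sets.  RMSF profiles follow the usual two-pass convention:
frames are aligned on the analysis selection, the time-average structure is
formed, frames are re-aligned to that average, and the per-residue
fluctuation is taken about it.

Distances in periodic systems use the minimum-image convention, supported
for cubic boxes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure_io import ComplexTopology, Role, SimulationBox, Trajectory, select_atoms

__all__ = [
    "SuperpositionResult",
    "RMSFProfile",
    "ContactSpec",
    "IonBindingSeries",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "min_image_displacement",
    "count_bound_ions",
    "ion_binding_series",
    "min_pair_distance_trace",
    "domain_rmsd_report",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference."""

    rotation: np.ndarray  # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,)
    rmsd: float  # Å

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RMSFProfile:
    """Per-residue root mean square fluctuation over an aligned trajectory."""

    residue_ids: np.ndarray
    rmsf: np.ndarray  # Å
    selection_label: str = ""
    n_frames: int = 0

    def __post_init__(self):
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if self.residue_ids.shape != self.rmsf.shape:
            raise ValueError("residue_ids and rmsf lengths differ")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue_id": self.residue_ids,
                             "rmsf_A": self.rmsf})


@dataclass(frozen=True)
class ContactSpec:
    """Ion-contact counting rule: bound iff min-image distance < cutoff."""

    probe_indices: np.ndarray  # ion atom indices
    target_indices: np.ndarray  # whole-complex atom indices
    duplex_indices: np.ndarray | None = None  # subset for duplex counts
    cutoff_A: float = 5.0  # strict "<"
    periodic: bool = True
    box: SimulationBox | None = None

    def __post_init__(self):
        if self.cutoff_A <= 0:
            raise ValueError("cutoff must be positive")
        if set(np.asarray(self.probe_indices).tolist()) & set(
                np.asarray(self.target_indices).tolist()):
            raise ValueError("probe and target atom sets must be disjoint")
        if self.periodic:
            if self.box is None:
                raise ValueError("periodic contact counting requires a box")
            if len(set(self.box.edge_lengths)) != 1:
                raise ValueError("only cubic periodic boxes are supported")


@dataclass
class IonBindingSeries:
    """Per-frame bound-ion counts against the whole complex and the duplex."""

    times_ps: np.ndarray
    bound_count_whole: np.ndarray
    bound_count_duplex: np.ndarray

    def __post_init__(self):
        if np.any(self.bound_count_duplex > self.bound_count_whole):
            raise ValueError("duplex-bound count exceeds whole-complex count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ps": self.times_ps,
            "bound_whole": self.bound_count_whole,
            "bound_duplex": self.bound_count_duplex,
        })


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     ) -> SuperpositionResult:
    """Least-squares optimal proper rigid transform of mobile onto reference.

    Reflections are suppressed: the returned rotation always has det = +1,
    so mirror-image point sets superpose with nonzero RMSD rather than
    through an improper transform.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"point counts differ: {mobile.shape} vs {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinates must be (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"superposition needs >= 3 points, got {n}")
    if not (np.isfinite(mobile).all() and np.isfinite(reference).all()):
        raise ValueError("coordinates must be finite")

    mob_mean = mobile.mean(axis=0)
    ref_mean = reference.mean(axis=0)
    mob_c = mobile - mob_mean
    ref_c = reference - ref_mean
    if (np.linalg.matrix_rank(mob_c, tol=1e-8) < 2
            or np.linalg.matrix_rank(ref_c, tol=1e-8) < 2):
        raise ValueError("degenerate input: fewer than 3 non-collinear points")

    cov = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = ref_mean - rotation @ mob_mean
    moved = mob_c @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref_c) ** 2, axis=1))))
    return SuperpositionResult(rotation, translation, rmsd)


def _align_frames(coords: np.ndarray, reference: np.ndarray,
                  fit_idx: np.ndarray) -> np.ndarray:
    """Superpose every frame onto reference using fit_idx atoms; transform all."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        res = kabsch_superpose(coords[f, fit_idx], reference[fit_idx])
        out[f] = res.transform(coords[f])
    return out


def rmsd_series(trajectory: Trajectory, reference_frame: np.ndarray,
                selection: np.ndarray, superpose: bool = True) -> pd.DataFrame:
    """Per-frame RMSD of the selection against a reference frame.

    With ``superpose`` each frame is first optimally aligned on the
    selection; otherwise raw coordinates are compared (drift included).
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    ref = np.asarray(reference_frame, dtype=float)[selection]
    vals = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        mob = trajectory.coords[f, selection]
        if superpose:
            vals[f] = kabsch_superpose(mob, ref).rmsd
        else:
            vals[f] = float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))
    return pd.DataFrame({"time_ps": trajectory.times_ps, "rmsd_A": vals})


def rmsf(trajectory: Trajectory, selection: np.ndarray,
         align: bool = True) -> RMSFProfile:
    """RMSF_i = sqrt(mean_t |r_i(t) - <r_i>|^2) over the aligned trajectory.

    The alignment reference is the post-alignment time-average structure,
    reached by one fixed-point pass: align to the raw time-average (so the
    result is invariant to frame order), average, re-align to the average.
    Alignment uses the same selection being profiled.  One value per selected atom; atoms of the same residue are
    reported individually only if the selection includes several (the usual
    Cα selection gives one per residue).
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    if trajectory.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    coords = trajectory.coords
    if align:
        # seed with the raw time-average (frame-order invariant), then one
        # fixed-point pass toward the aligned average
        coords = _align_frames(coords, coords.mean(axis=0), selection)
        coords = _align_frames(coords, coords.mean(axis=0), selection)
    sub = coords[:, selection]
    mean = sub.mean(axis=0)
    vals = np.sqrt(np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0))
    rids = trajectory.topology.residue_ids[selection]
    return RMSFProfile(rids, vals, n_frames=trajectory.n_frames)


# ---------------------------------------------------------------------------
# Periodic distances and ion contacts
# ---------------------------------------------------------------------------

def min_image_displacement(delta: np.ndarray, box: SimulationBox) -> np.ndarray:
    """Wrap displacement vectors to their nearest periodic image (cubic box)."""
    if len(set(box.edge_lengths)) != 1:
        raise ValueError("minimum-image convention requires a cubic box")
    edge = box.edge
    return delta - edge * np.round(delta / edge)


def _min_dists(probes: np.ndarray, targets: np.ndarray,
               periodic: bool, box: SimulationBox | None) -> np.ndarray:
    """Minimum distance from each probe point to the target set."""
    delta = probes[:, None, :] - targets[None, :, :]
    if periodic:
        delta = min_image_displacement(delta, box)
    d = np.sqrt(np.sum(delta ** 2, axis=2))
    return d.min(axis=1)


def count_bound_ions(frame: np.ndarray, spec: ContactSpec
                     ) -> tuple[int, int]:
    """Bound-ion counts for one frame: (whole complex, duplex subset).

    An ion is bound iff its minimum-image distance to any target atom is
    strictly below the cutoff; an ion exactly at the cutoff is free.
    """
    frame = np.asarray(frame, dtype=float)
    probes = frame[np.asarray(spec.probe_indices, dtype=int)]
    targets = frame[np.asarray(spec.target_indices, dtype=int)]
    whole = int(np.sum(_min_dists(probes, targets, spec.periodic, spec.box)
                       < spec.cutoff_A))
    duplex = 0
    if spec.duplex_indices is not None and len(spec.duplex_indices) > 0:
        dtargets = frame[np.asarray(spec.duplex_indices, dtype=int)]
        duplex = int(np.sum(_min_dists(probes, dtargets, spec.periodic,
                                       spec.box) < spec.cutoff_A))
    return whole, duplex


def ion_binding_series(trajectory: Trajectory, spec: ContactSpec
                       ) -> IonBindingSeries:
    whole = np.empty(trajectory.n_frames, dtype=int)
    duplex = np.empty(trajectory.n_frames, dtype=int)
    for f in range(trajectory.n_frames):
        whole[f], duplex[f] = count_bound_ions(trajectory.coords[f], spec)
    return IonBindingSeries(trajectory.times_ps.copy(), whole, duplex)


# ---------------------------------------------------------------------------
# Closest-pair traces and domain reports
# ---------------------------------------------------------------------------

def min_pair_distance_trace(trajectory: Trajectory, set_a: np.ndarray,
                            set_b: np.ndarray) -> pd.DataFrame:
    """Per frame, the closest inter-set atom distance and its residue pair.

    Ties resolve to the numerically lowest (residue_a, residue_b) pair.
    """
    set_a = np.asarray(set_a, dtype=int)
    set_b = np.asarray(set_b, dtype=int)
    if set_a.size == 0 or set_b.size == 0:
        raise ValueError("both atom sets must be non-empty")
    if set(set_a.tolist()) & set(set_b.tolist()):
        raise ValueError("atom sets must be disjoint")
    rids = trajectory.topology.residue_ids
    rows = []
    for f in range(trajectory.n_frames):
        d = cdist(trajectory.coords[f, set_a], trajectory.coords[f, set_b])
        dmin = d.min()
        ia, ib = np.where(d <= dmin + 1e-12)
        pairs = sorted(
            (int(rids[set_a[i]]), int(rids[set_b[j]])) for i, j in zip(ia, ib)
        )
        ra, rb = pairs[0]
        rows.append((trajectory.times_ps[f], ra, rb, float(dmin)))
    return pd.DataFrame(rows, columns=["time_ps", "residue_a", "residue_b",
                                       "distance_A"])


def domain_rmsd_report(
    topology_a: ComplexTopology,
    frame_a: np.ndarray,
    topology_b: ComplexTopology,
    frame_b: np.ndarray,
    heavy_only: bool = True,
) -> pd.DataFrame:
    """Per-domain and whole-protein superposition RMSDs between two structures.

    Each domain (PAZ = union of its two subranges, MID, PIWI) and the whole
    protein is independently superposed over the atoms common to both
    structures, matched by (chain, residue, atom name).  A domain with no
    common atoms is flagged, not dropped.
    """
    def keyed(topo: ComplexTopology, idx: np.ndarray) -> dict:
        return {
            (topo.chain_ids[i], int(topo.residue_ids[i]), topo.atom_names[i]): i
            for i in idx
        }

    dm = topology_a.domain_map.merged()
    regions: dict[str, set[int] | None] = dict(sorted(dm.items()))
    regions["whole"] = None

    rows = []
    for name, resids in regions.items():
        kw = dict(roles=[Role.PROTEIN], heavy_only=heavy_only)
        if resids is not None:
            ranges = _ranges_from_set(resids)
            idx_a = select_atoms(topology_a, residue_ranges=ranges, **kw)
            idx_b = select_atoms(topology_b, residue_ranges=ranges, **kw)
        else:
            idx_a = select_atoms(topology_a, **kw)
            idx_b = select_atoms(topology_b, **kw)
        ka, kb = keyed(topology_a, idx_a), keyed(topology_b, idx_b)
        common = sorted(set(ka) & set(kb), key=lambda k: ka[k])
        if len(common) < 3:
            rows.append((name, len(common), np.nan, True))
            continue
        a = frame_a[[ka[k] for k in common]]
        b = frame_b[[kb[k] for k in common]]
        rows.append((name, len(common), kabsch_superpose(b, a).rmsd, False))
    return pd.DataFrame(rows, columns=["domain", "n_atoms", "rmsd_A",
                                       "flagged"])


def _ranges_from_set(resids: set[int]) -> list[tuple[int, int]]:
    """Collapse a residue-id set into inclusive contiguous ranges."""
    out = []
    ids = sorted(resids)
    start = prev = ids[0]
    for r in ids[1:]:
        if r != prev + 1:
            out.append((start, prev))
            start = r
        prev = r
    out.append((start, prev))
    return out
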