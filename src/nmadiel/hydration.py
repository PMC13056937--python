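"""Shell assignment of waters around a protein and persistence statistics.

Distances are minimum distances from a water's reference point (its first
atom per residue — conventionally the oxygen) to any protein atom; shells
are half-open distance bands [edge, next_edge) in Angstrom.  Coordinates in
the domain types are nm; conversion happens here.  No minimum-image
handling: synthetic inputs are non-periodic and real trajectories must be
pre-wrapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .modes import AtomSet
from .synthetic import ShellTrajectory

__all__ = [
    "PersistenceResult",
    "assign_shells",
    "shell_trajectory_from_frames",
    "persistence_fraction",
    "count_bound_waters",
]

NM_TO_ANGSTROM = 10.0


@dataclass(frozen=True)
class PersistenceResult:
    """Percentage of each shell's occupants that persist >= threshold.

    ``per_frame_percent`` has shape (n_valid_frames, n_shells); entries are
    NaN when a shell is unoccupied at that frame.  Frame f covers waters
    present in a shell at f that stay there through the following
    ceil(threshold/dt) frames.
    """

    per_frame_percent: np.ndarray
    threshold_ps: float
    boundaries: np.ndarray
    n_occupants: np.ndarray | None = None
    n_persistent: np.ndarray | None = None

    def shell_means(self) -> np.ndarray:
        """Per-shell mean percentage over frames, ignoring unoccupied frames."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.per_frame_percent, axis=0)


def assign_shells(
    protein_coords_nm: np.ndarray,
    water_coords_nm: np.ndarray,
    boundaries_angstrom=(0.0, 3.0, 5.0, 7.0, 9.0),
) -> np.ndarray:
    """Shell index per water from its minimum distance to any protein atom.

    Returns integers in {0..n_shells-1}, or -1 beyond the last edge.
    """
    protein = np.asarray(protein_coords_nm, dtype=float)
    water = np.asarray(water_coords_nm, dtype=float)
    if protein.size == 0 or water.size == 0:
        raise ValueError("protein and water coordinate sets must be nonempty")
    bounds = np.asarray(boundaries_angstrom, dtype=float)
    if np.any(np.diff(bounds) <= 0):
        raise ValueError("boundaries must be strictly increasing")
    if bounds[0] != 0.0:
        raise ValueError("boundaries must start at 0")
    tree = cKDTree(protein)
    dmin_a = tree.query(water)[0] * NM_TO_ANGSTROM
    # np.searchsorted with side='right' puts d on [edge_k, edge_{k+1}) in band k
    shell = np.searchsorted(bounds, dmin_a, side="right") - 1
    shell[dmin_a >= bounds[-1]] = -1
    return shell.astype(int)


def shell_trajectory_from_frames(
    protein_frames_nm: np.ndarray,
    water_frames_nm: np.ndarray,
    boundaries_angstrom=(0.0, 3.0, 5.0, 7.0, 9.0),
    frame_spacing_ps: float = 20.0,
) -> ShellTrajectory:
    """Assign shells frame-by-frame for coordinate trajectories."""
    protein_frames = np.asarray(protein_frames_nm, dtype=float)
    water_frames = np.asarray(water_frames_nm, dtype=float)
    if protein_frames.shape[0] != water_frames.shape[0]:
        raise ValueError("protein and water trajectories differ in frame count")
    idx = np.stack(
        [
            assign_shells(protein_frames[f], water_frames[f], boundaries_angstrom)
            for f in range(protein_frames.shape[0])
        ]
    )
    return ShellTrajectory(
        shell_index=idx,
        frame_spacing_ps=frame_spacing_ps,
        boundaries=np.asarray(boundaries_angstrom, dtype=float),
    )


def persistence_fraction(
    traj: ShellTrajectory, threshold_ps: float
) -> PersistenceResult:
    """Per-frame percentage of each shell's waters persisting >= threshold.

    A water in shell s at frame f is persistent if it stays in s for the
    next ceil(threshold/dt) frames (forward-looking); with threshold equal
    to the frame spacing that is simply shell(f+1) == shell(f).  Waters
    outside all shells (-1) are not occupants of any shell.
    """
    if threshold_ps < traj.frame_spacing_ps:
        raise ValueError(
            f"threshold {threshold_ps} ps is below the frame spacing "
            f"{traj.frame_spacing_ps} ps and cannot be resolved"
        )
    n_ahead = int(np.ceil(threshold_ps / traj.frame_spacing_ps))
    idx = traj.shell_index
    n_frames, _ = idx.shape
    n_valid = n_frames - n_ahead
    if n_valid < 1:
        raise ValueError("trajectory too short for the requested threshold")
    n_shells = traj.n_shells
    percent = np.full((n_valid, n_shells), np.nan)
    occupants = np.zeros((n_valid, n_shells), dtype=int)
    persistent = np.zeros((n_valid, n_shells), dtype=int)
    stays = np.ones((n_valid, idx.shape[1]), dtype=bool)
    for k in range(1, n_ahead + 1):
        stays &= idx[k : n_valid + k] == idx[:n_valid]
    for s in range(n_shells):
        occupant = idx[:n_valid] == s
        n_occ = occupant.sum(axis=1)
        n_per = (occupant & stays).sum(axis=1)
        occupants[:, s] = n_occ
        persistent[:, s] = n_per
        percent[:, s] = np.where(
            n_occ > 0, 100.0 * n_per / np.maximum(n_occ, 1), np.nan
        )
    return PersistenceResult(
        per_frame_percent=percent,
        threshold_ps=float(threshold_ps),
        boundaries=traj.boundaries.copy(),
        n_occupants=occupants,
        n_persistent=persistent,
    )


def count_bound_waters(
    atoms: AtomSet,
    cutoff_angstrom: float = 3.0,
    water_reference: str = "first-atom",
) -> int:
    """Number of water residues whose reference point is within cutoff of protein.

    ``water_reference`` selects the residue's first atom (oxygen by the
    usual ordering) or ``"com"`` for its center of mass.
    """
    if cutoff_angstrom <= 0:
        raise ValueError("cutoff must be positive")
    if atoms.coordinates is None:
        raise ValueError("AtomSet has no coordinates")
    protein_mask = atoms.component_mask("protein")
    water_mask = atoms.component_mask("water") if (atoms.component_labels == "water").any() else None
    if not protein_mask.any():
        raise ValueError("no protein atoms present")
    if water_mask is None:
        return 0
    coords = atoms.coordinates
    refs = []
    water_resids = atoms.residue_indices[water_mask]
    for resid in np.unique(water_resids):
        sel = water_mask & (atoms.residue_indices == resid)
        if water_reference == "com":
            w = atoms.masses[sel]
            refs.append(np.average(coords[sel], axis=0, weights=w))
        else:
            refs.append(coords[sel][0])
    refs = np.asarray(refs)
    tree = cKDTree(coords[protein_mask])
    dmin_a = tree.query(refs)[0] * NM_TO_ANGSTROM
    return int(np.sum(dmin_a <= cutoff_angstrom))
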