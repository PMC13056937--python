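"""Per-mode dipole-variation vectors, component angles and residue profiles.

The dipole-variation (dipole-derivative) vector of mode l is the
charge-weighted sum of its Cartesian eigenvector components,
``sum_i q_i e_{l,i}`` (C kg^-1/2); its Euclidean norm rho_l is the effective
charge that couples the mode to an external field.  Restricting the sum to a
component (protein / water / ligand) uses the WHOLE system's eigenvectors —
only the charge sum is restricted — so component vectors add exactly across
any partition of the atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .modes import AtomSet, ModeEnsemble, ModeSet

__all__ = [
    "DipoleTable",
    "AngleTable",
    "mode_dipole",
    "component_angles",
    "ensemble_angle_profile",
    "residue_displacement_profile",
]


@dataclass(frozen=True)
class DipoleTable:
    """Per-mode dipole-variation vectors (C kg^-1/2) for one atom subset."""

    component: str
    vectors: np.ndarray  # (M, 3)
    magnitudes: np.ndarray  # (M,)
    mode_frequencies: np.ndarray  # Hz, copied from the mode set

    @property
    def n_modes(self) -> int:
        return int(self.magnitudes.size)


@dataclass(frozen=True)
class AngleTable:
    """Angles (degrees, [0, 180]) between two components' dipole vectors.

    ``angles`` is per mode (NaN where either vector vanishes).  For ensemble
    profiles, ``mean`` / ``sd`` / ``n_defined`` are per ascending-frequency
    mode rank across replicas.
    """

    angles: np.ndarray | None = None
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None
    n_defined: np.ndarray | None = None


def _resolve_subset(atoms: AtomSet, subset) -> np.ndarray:
    """Turn a component name, label list or index array into a boolean mask."""
    if isinstance(subset, str) or (
        isinstance(subset, (list, tuple)) and all(isinstance(s, str) for s in subset)
    ):
        mask = atoms.component_mask(subset)
    else:
        idx = np.asarray(subset)
        if idx.dtype == bool:
            if idx.size != atoms.n_atoms:
                raise ValueError("boolean subset mask has wrong length")
            mask = idx
        else:
            idx = idx.astype(int)
            if idx.size and (idx.min() < 0 or idx.max() >= atoms.n_atoms):
                raise ValueError("subset indices outside the atom set")
            mask = np.zeros(atoms.n_atoms, dtype=bool)
            mask[idx] = True
    if not mask.any():
        raise ValueError(f"subset {subset!r} selects no atoms")
    return mask


def mode_dipole(modeset: ModeSet, subset="whole") -> DipoleTable:
    """Compute dipole-variation vectors with the charge sum over ``subset``."""
    mask = _resolve_subset(modeset.atoms, subset)
    q = modeset.atoms.charges * mask
    vectors = np.einsum("i,lic->lc", q, modeset.eigenvectors)
    label = subset if isinstance(subset, str) else "custom"
    return DipoleTable(
        component=label,
        vectors=vectors,
        magnitudes=np.linalg.norm(vectors, axis=1),
        mode_frequencies=modeset.mode_frequencies.copy(),
    )


def component_angles(dipoles_a: DipoleTable, dipoles_b: DipoleTable) -> AngleTable:
    """Per-mode angle between two dipole tables' vectors, in degrees.

    Modes where either magnitude is zero get NaN (angle undefined); callers
    must exclude them from means rather than treating them as 0.
    """
    if dipoles_a.n_modes != dipoles_b.n_modes:
        raise ValueError(
            f"mode-count mismatch: {dipoles_a.n_modes} vs {dipoles_b.n_modes}"
        )
    a, b = dipoles_a.vectors, dipoles_b.vectors
    na, nb = dipoles_a.magnitudes, dipoles_b.magnitudes
    defined = (na > 0) & (nb > 0)
    cos = np.full(dipoles_a.n_modes, np.nan)
    with np.errstate(invalid="ignore"):
        cos[defined] = np.einsum("lc,lc->l", a, b)[defined] / (na * nb)[defined]
    cos = np.clip(cos, -1.0, 1.0)
    return AngleTable(angles=np.degrees(np.arccos(cos)))


def ensemble_angle_profile(
    ensemble: ModeEnsemble, subset_a, subset_b, n_modes: int
) -> AngleTable:
    """Mean/sd of the inter-component angle per mode rank across replicas.

    Modes are matched across replicas by ascending-frequency rank.  Undefined
    angles (zero-magnitude vectors) are excluded; ``n_defined`` reports how
    many replicas contributed at each rank.
    """
    if n_modes > ensemble.n_modes:
        raise ValueError(
            f"requested {n_modes} modes but replicas have {ensemble.n_modes}"
        )
    per_replica = np.empty((ensemble.n_replicas, n_modes))
    for r, modeset in enumerate(ensemble):
        table = component_angles(
            mode_dipole(modeset, subset_a), mode_dipole(modeset, subset_b)
        )
        per_replica[r] = table.angles[:n_modes]
    defined = ~np.isnan(per_replica)
    n_def = defined.sum(axis=0)
    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.where(n_def > 0, np.nanmean(per_replica, axis=0), np.nan)
        sd = np.where(n_def > 1, np.nanstd(per_replica, axis=0, ddof=1), 0.0)
        sd = np.where(n_def > 0, sd, np.nan)
    return AngleTable(mean=mean, sd=sd, n_defined=n_def)


def residue_displacement_profile(modeset: ModeSet, mode_index: int) -> np.ndarray:
    """Per-residue RMS eigenvector displacement for one mode (kg^-1/2).

    For residue r: sqrt(mean over its atoms of |e_{l,i}|^2).  Returned in
    ascending residue-index order alongside no labels; pair with
    ``np.unique(modeset.atoms.residue_indices)`` for the axis.
    """
    if not 0 <= mode_index < modeset.n_modes:
        raise IndexError(f"mode_index {mode_index} out of range [0, {modeset.n_modes})")
    sq = np.sum(modeset.eigenvectors[mode_index] ** 2, axis=1)
    resids = modeset.atoms.residue_indices
    unique, inverse = np.unique(resids, return_inverse=True)
    sums = np.bincount(inverse, weights=sq)
    counts = np.bincount(inverse)
    return np.sqrt(sums / counts)
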