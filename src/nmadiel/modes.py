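"""Domain types and core operations for normal-mode ensembles.

A :class:`ModeSet` binds one replica's mode frequencies (Hz, linear
frequency) and Cartesian mass-weighted eigenvectors (kg^-1/2) to the atom
metadata of an :class:`AtomSet`.  Frequencies are always stored in Hz;
wavenumber input is converted at the boundary with
:func:`wavenumber_to_frequency`.  Charges are stored in Coulomb; masses in kg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import CM1_TO_HZ

__all__ = [
    "COMPONENTS",
    "AtomSet",
    "ModeSet",
    "ModeEnsemble",
    "VDOSHistogram",
    "wavenumber_to_frequency",
    "select_vibrational_modes",
    "mode_density",
]

#: Recognized component labels.
COMPONENTS = ("protein", "water", "ligand")

#: Default frequency below which a mode counts as rigid-body, Hz (1 GHz).
DEFAULT_ZERO_TOLERANCE_HZ = 1e9

#: Mass-weighted orthonormality tolerance for accepted mode sets.
ORTHONORMALITY_TOL = 1e-8


class ValidationError(ValueError):
    """An invariant of a domain type is violated."""


@dataclass(frozen=True)
class AtomSet:
    """Per-atom metadata: masses (kg), charges (C), labels, residue indices.

    ``coordinates`` (nm, shape (N, 3)) are optional and only required by the
    hydration / bound-water operations.
    """

    masses: np.ndarray
    charges: np.ndarray
    component_labels: np.ndarray
    residue_indices: np.ndarray
    coordinates: np.ndarray | None = None

    def __post_init__(self) -> None:
        masses = np.asarray(self.masses, dtype=float)
        charges = np.asarray(self.charges, dtype=float)
        labels = np.asarray(self.component_labels, dtype=object)
        resids = np.asarray(self.residue_indices, dtype=int)
        n = masses.size
        if not (charges.size == labels.size == resids.size == n):
            raise ValidationError("per-atom arrays must have equal length")
        if n == 0:
            raise ValidationError("AtomSet must contain at least one atom")
        if not np.all(masses > 0):
            raise ValidationError("masses must be strictly positive")
        if not np.all(np.isfinite(charges)):
            raise ValidationError("charges must be finite")
        unknown = set(labels.tolist()) - set(COMPONENTS)
        if unknown:
            raise ValidationError(f"unknown component labels: {sorted(unknown)}")
        object.__setattr__(self, "masses", masses)
        object.__setattr__(self, "charges", charges)
        object.__setattr__(self, "component_labels", labels)
        object.__setattr__(self, "residue_indices", resids)
        if self.coordinates is not None:
            coords = np.asarray(self.coordinates, dtype=float)
            if coords.shape != (n, 3):
                raise ValidationError(
                    f"coordinates must have shape ({n}, 3), got {coords.shape}"
                )
            object.__setattr__(self, "coordinates", coords)

    @property
    def n_atoms(self) -> int:
        return int(self.masses.size)

    def component_mask(self, component: str | Sequence[str]) -> np.ndarray:
        """Boolean mask selecting atoms whose label is in ``component``.

        ``"whole"`` selects every atom.
        """
        if isinstance(component, str):
            if component == "whole":
                return np.ones(self.n_atoms, dtype=bool)
            component = [component]
        return np.isin(self.component_labels, list(component))


@dataclass(frozen=True)
class ModeSet:
    """One replica's frequencies (Hz) and mass-weighted eigenvectors.

    ``eigenvectors`` has shape (M, N, 3) in kg^-1/2 (Cartesian output of a
    mass-weighted Hessian diagonalization, already divided by sqrt(m_i)).
    Imaginary-frequency modes (negative Hessian eigenvalues) are flagged by a
    negative entry in ``mode_frequencies``, mirroring the wavenumber-sign
    convention of common NMA tools; they are rejected by
    :func:`select_vibrational_modes` beyond the zero tolerance.
    """

    atoms: AtomSet
    mode_frequencies: np.ndarray
    eigenvectors: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.mode_frequencies, dtype=float)
        vecs = np.asarray(self.eigenvectors, dtype=float)
        if vecs.ndim != 3 or vecs.shape[2] != 3:
            raise ValidationError(
                f"eigenvectors must have shape (M, N, 3), got {vecs.shape}"
            )
        if vecs.shape[0] != freqs.size:
            raise ValidationError("frequency count does not match eigenvector count")
        if vecs.shape[1] != self.atoms.n_atoms:
            raise ValidationError(
                f"eigenvector atom count {vecs.shape[1]} != "
                f"AtomSet count {self.atoms.n_atoms}"
            )
        if np.any(np.diff(freqs) < 0):
            raise ValidationError("mode frequencies must be sorted ascending")
        object.__setattr__(self, "mode_frequencies", freqs)
        object.__setattr__(self, "eigenvectors", vecs)

    @property
    def n_modes(self) -> int:
        return int(self.mode_frequencies.size)

    @property
    def degrees_of_freedom(self) -> int:
        """Vibrational degrees of freedom 3N - 6 of the underlying system."""
        return 3 * self.atoms.n_atoms - 6

    def check_orthonormality(self, tol: float = ORTHONORMALITY_TOL) -> None:
        """Verify sum_i m_i e_l,i . e_l',i = delta_ll' within ``tol``.

        Raises :class:`ValidationError` naming the worst offending mode pair.
        """
        m = self.atoms.masses
        # (M, 3N) mass-weighted rows
        u = (self.eigenvectors * np.sqrt(m)[None, :, None]).reshape(self.n_modes, -1)
        gram = u @ u.T
        dev = np.abs(gram - np.eye(self.n_modes))
        worst = np.unravel_index(np.argmax(dev), dev.shape)
        if dev[worst] > tol:
            raise ValidationError(
                "mass-weighted orthonormality violated: modes "
                f"{worst[0]} and {worst[1]} deviate by {dev[worst]:.3e} (tol {tol:g})"
            )


@dataclass(frozen=True)
class ModeEnsemble:
    """An ordered collection of replicas sharing one atom topology."""

    replicas: tuple[ModeSet, ...]
    shared_topology: bool = True

    def __post_init__(self) -> None:
        reps = tuple(self.replicas)
        if not reps:
            raise ValidationError("ensemble must contain at least one replica")
        n_atoms = {r.atoms.n_atoms for r in reps}
        n_modes = {r.n_modes for r in reps}
        if len(n_atoms) > 1 or len(n_modes) > 1:
            raise ValidationError(
                f"replicas disagree: n_atoms={sorted(n_atoms)}, n_modes={sorted(n_modes)}"
            )
        object.__setattr__(self, "replicas", reps)

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    @property
    def n_modes(self) -> int:
        return self.replicas[0].n_modes

    def __iter__(self):
        return iter(self.replicas)


@dataclass(frozen=True)
class VDOSHistogram:
    """Mode counts per frequency bin with per-degree-of-freedom normalization.

    ``normalized`` holds g_n = n_j / (N_f * dnu), the per-DOF density of
    states on the linear-frequency axis.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    bin_width: float
    degrees_of_freedom: int
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=int)
        if counts.size != edges.size - 1:
            raise ValidationError("counts must have one entry fewer than edges")
        if np.any(counts < 0):
            raise ValidationError("bin counts must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        gn = counts / (self.degrees_of_freedom * self.bin_width)
        object.__setattr__(self, "normalized", gn)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def wavenumber_to_frequency(wavenumber):
    """Convert wavenumber (cm^-1) to linear frequency (Hz).

    nu = 2.99792458e10 * nu_tilde.  Negative input raises ``ValueError``.
    """
    wn = np.asarray(wavenumber, dtype=float)
    if np.any(wn < 0):
        raise ValueError("wavenumber must be non-negative")
    out = CM1_TO_HZ * wn
    return float(out) if np.isscalar(wavenumber) or out.ndim == 0 else out


def select_vibrational_modes(
    modeset: ModeSet,
    max_modes: int | None = None,
    zero_tolerance: float = DEFAULT_ZERO_TOLERANCE_HZ,
) -> ModeSet:
    """Drop rigid-body modes, reject imaginary frequencies, truncate.

    The six smallest-|nu| modes below ``zero_tolerance`` are removed before
    counting the retained modes (a rigid mode would produce a divergent
    nu_l -> 0 Lorentz term downstream).  A negative frequency whose magnitude
    exceeds the tolerance signals a negative Hessian eigenvalue, i.e. an
    incompletely minimized structure, and raises ``ValueError``.
    """
    freqs = modeset.mode_frequencies
    if np.any(freqs < -zero_tolerance):
        bad = np.nonzero(freqs < -zero_tolerance)[0]
        raise ValueError(
            f"imaginary-frequency modes beyond tolerance at indices {bad.tolist()}: "
            "structure is not at a potential-energy minimum"
        )
    near_zero = np.abs(freqs) < zero_tolerance
    n_zero = int(near_zero.sum())
    if n_zero < 6:
        warnings.warn(
            f"only {n_zero} modes below zero tolerance {zero_tolerance:g} Hz; "
            "expected 6 rigid-body modes for a nonlinear 3-D system",
            stacklevel=2,
        )
    # remove the 6 (or fewer, if fewer qualify) smallest-|nu| modes
    n_remove = min(6, n_zero)
    order = np.argsort(np.abs(freqs), kind="stable")
    removed = set(order[:n_remove].tolist())
    keep = np.array([i for i in range(freqs.size) if i not in removed], dtype=int)
    if max_modes is not None:
        keep = keep[:max_modes]
    return replace(
        modeset,
        mode_frequencies=freqs[keep],
        eigenvectors=modeset.eigenvectors[keep],
    )


def mode_density(modeset: ModeSet, bin_width: float) -> VDOSHistogram:
    """Histogram mode frequencies into half-open bins of width ``bin_width`` Hz.

    Bins cover [min nu, max nu] with membership [edge, edge + width), so no
    mode is counted twice; counts conserve the number of binned modes.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    freqs = modeset.mode_frequencies
    if freqs.size == 0:
        raise ValueError("cannot histogram an empty mode set")
    lo = float(freqs.min())
    hi = float(freqs.max())
    n_bins = int(np.floor((hi - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    idx = np.clip(np.floor((freqs - lo) / bin_width).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return VDOSHistogram(
        bin_edges=edges,
        counts=counts,
        bin_width=float(bin_width),
        degrees_of_freedom=modeset.degrees_of_freedom,
    )
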