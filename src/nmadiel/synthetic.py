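"""Toy harmonic systems with exact analytic Hessians, plus Markov shell chains.

These systems stand in for energy-minimized protein structures: springs are
relaxed at the generated geometry (rest length equals the equilibrium
distance), so the pairwise Hessian block is exactly ``-k n n^T`` with ``n``
the unit bond vector and no minimizer is needed.  A generically rigid spring
network then has exactly six zero modes (rigid translations and rotations).

Spring constants are in N/m, coordinates in nm, masses in amu at the
interface (converted to kg internally), charges in elementary-charge units.
With k ~ 0.01-1 N/m and amu-scale masses the mode frequencies land in the
sub-THz band the downstream spectra modules target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import ATOMIC_MASS, ELEMENTARY_CHARGE
from .modes import AtomSet, ModeEnsemble, ModeSet

__all__ = [
    "HarmonicSystem",
    "ShellTrajectory",
    "build_harmonic_system",
    "solve_modes",
    "synth_hydrated_variant",
    "synth_mode_ensemble",
    "synth_shell_trajectory",
]

#: Relative eigenvalue threshold below which a mode counts as a zero mode.
ZERO_EIGENVALUE_RTOL = 1e-9


@dataclass(frozen=True)
class HarmonicSystem:
    """A spring network at mechanical equilibrium with its exact Hessian.

    ``springs`` rows are (i, j, k_spring N/m, rest_length nm); ``hessian`` is
    the 3N x 3N second-derivative matrix in N/m.
    """

    atoms: AtomSet
    springs: np.ndarray
    hessian: np.ndarray

    @property
    def n_atoms(self) -> int:
        return self.atoms.n_atoms


@dataclass(frozen=True)
class ShellTrajectory:
    """Per-frame shell assignment of each water molecule.

    ``shell_index`` has shape (n_frames, n_waters) with values in
    {0..n_shells-1} or -1 (outside all shells); ``boundaries`` are the shell
    edges in Angstrom, strictly increasing.
    """

    shell_index: np.ndarray
    frame_spacing_ps: float
    boundaries: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.shell_index, dtype=int)
        bounds = np.asarray(self.boundaries, dtype=float)
        if idx.ndim != 2:
            raise ValueError("shell_index must be (n_frames, n_waters)")
        if np.any(np.diff(bounds) <= 0):
            raise ValueError("shell boundaries must be strictly increasing")
        n_shells = bounds.size - 1
        if np.any(idx < -1) or np.any(idx >= n_shells):
            raise ValueError("shell_index out of range")
        object.__setattr__(self, "shell_index", idx)
        object.__setattr__(self, "boundaries", bounds)

    @property
    def n_frames(self) -> int:
        return int(self.shell_index.shape[0])

    @property
    def n_waters(self) -> int:
        return int(self.shell_index.shape[1])

    @property
    def n_shells(self) -> int:
        return int(self.boundaries.size - 1)


def _pairwise_hessian(coords: np.ndarray, springs: np.ndarray) -> np.ndarray:
    """Exact Hessian of relaxed harmonic springs: block -k n n^T per spring."""
    n = coords.shape[0]
    h = np.zeros((3 * n, 3 * n))
    for i, j, k, _rest in springs:
        i, j = int(i), int(j)
        d = coords[i] - coords[j]
        nhat = d / np.linalg.norm(d)
        block = k * np.outer(nhat, nhat)
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        h[si, si] += block
        h[sj, sj] += block
        h[si, sj] -= block
        h[sj, si] -= block
    return h


def _count_zero_modes(system: HarmonicSystem) -> int:
    m = np.repeat(system.atoms.masses, 3)
    d = system.hessian / np.sqrt(np.outer(m, m))
    evals = np.linalg.eigvalsh(d)
    scale = max(evals.max(), 1.0)
    return int(np.sum(np.abs(evals) < ZERO_EIGENVALUE_RTOL * scale))


def _chain_coords(n_atoms: int, spacing: float = 0.15) -> np.ndarray:
    """Helical chain geometry: non-collinear, non-planar, generically rigid."""
    t = np.arange(n_atoms) * 0.9
    return spacing * np.column_stack(
        [np.cos(t), np.sin(t), 0.35 * t]
    )


def _ring_coords(n_atoms: int, radius: float = 0.3) -> np.ndarray:
    t = 2 * np.pi * np.arange(n_atoms) / n_atoms
    z = 0.08 * radius * np.cos(3 * t + 0.5)  # pucker: avoid planar floppiness
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), z])


def _chain_springs(n_atoms: int, k: float, coords: np.ndarray, wrap: bool) -> list:
    springs = []
    pairs = set()
    for offset in (1, 2, 3):
        limit = n_atoms if wrap else n_atoms - offset
        for i in range(max(0, limit)):
            j = (i + offset) % n_atoms
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in pairs:
                continue
            pairs.add(key)
            rest = float(np.linalg.norm(coords[i] - coords[j]))
            springs.append((i, j, k, rest))
    return springs


def build_harmonic_system(
    topology: str,
    n_atoms: int,
    masses_amu=12.0,
    charges_e=0.0,
    spring_constant: float = 0.1,
    seed: int = 0,
    component_labels=None,
    max_tries: int = 20,
) -> HarmonicSystem:
    """Build a deterministic spring network at equilibrium.

    ``topology`` is one of ``"chain"`` (helix with 1st-3rd neighbour
    springs), ``"ring"`` (puckered ring, same connectivity, wrapped) or
    ``"random"`` (uniform points joined to their nearest neighbours;
    regenerated with derived seeds until exactly six zero modes remain).
    """
    if n_atoms < 2:
        raise ValueError("n_atoms must be >= 2")
    if spring_constant <= 0:
        raise ValueError("spring_constant must be positive")
    masses = np.broadcast_to(np.asarray(masses_amu, dtype=float), (n_atoms,)).copy()
    charges = np.broadcast_to(np.asarray(charges_e, dtype=float), (n_atoms,)).copy()
    if component_labels is None:
        component_labels = np.full(n_atoms, "protein", dtype=object)
    else:
        component_labels = np.asarray(component_labels, dtype=object)

    for attempt in range(max_tries):
        rng = np.random.default_rng(seed + 7919 * attempt)
        if topology == "chain":
            coords = _chain_coords(n_atoms)
            springs = _chain_springs(n_atoms, spring_constant, coords, wrap=False)
        elif topology == "ring":
            if n_atoms < 3:
                raise ValueError("ring topology needs n_atoms >= 3")
            coords = _ring_coords(n_atoms)
            springs = _chain_springs(n_atoms, spring_constant, coords, wrap=True)
        elif topology == "random":
            coords = rng.uniform(0.0, 0.5 * n_atoms ** (1 / 3), size=(n_atoms, 3))
            k_neigh = min(n_atoms - 1, 5)
            springs, pairs = [], set()
            for i in range(n_atoms):
                d = np.linalg.norm(coords - coords[i], axis=1)
                for j in np.argsort(d)[1 : k_neigh + 1]:
                    key = (min(i, int(j)), max(i, int(j)))
                    if key in pairs:
                        continue
                    pairs.add(key)
                    springs.append((i, int(j), spring_constant, float(d[j])))
        else:
            raise ValueError(f"unknown topology {topology!r}")

        springs_arr = np.array(springs, dtype=float)
        atoms = AtomSet(
            masses=masses * ATOMIC_MASS,
            charges=charges * ELEMENTARY_CHARGE,
            component_labels=component_labels,
            residue_indices=np.arange(n_atoms) // 2,
            coordinates=coords,
        )
        system = HarmonicSystem(
            atoms=atoms, springs=springs_arr, hessian=_pairwise_hessian(coords, springs_arr)
        )
        expected_zero = _expected_zero_modes(coords, n_atoms)
        if _count_zero_modes(system) == expected_zero:
            return system
        if topology != "random":
            break
    raise ValueError(
        f"could not generate a generically rigid {topology!r} network of "
        f"{n_atoms} atoms (floppy or disconnected after {max_tries} tries)"
    )


def _expected_zero_modes(coords: np.ndarray, n_atoms: int) -> int:
    if n_atoms == 2:
        return 5  # linear molecule: 3 translations + 2 rotations
    # collinearity check
    rel = coords - coords[0]
    if np.linalg.matrix_rank(rel, tol=1e-10) < 2:
        return 5
    return 6


def solve_modes(system: HarmonicSystem, check_tol: float = 1e-9) -> ModeSet:
    """Diagonalize the mass-weighted Hessian and return Cartesian modes.

    M^(-1/2) H M^(-1/2) is diagonalized; eigenvalue lambda_l (angular
    frequency squared) maps to nu_l = sqrt(lambda_l)/(2 pi), and the
    orthonormal mass-weighted eigenvector u is divided by sqrt(m_i) to give
    Cartesian components in kg^-1/2.  A negative eigenvalue beyond
    ``check_tol`` (relative to the largest) raises ``ValueError``.
    """
    n = system.n_atoms
    m = np.repeat(system.atoms.masses, 3)
    inv_sqrt_m = 1.0 / np.sqrt(m)
    d = system.hessian * np.outer(inv_sqrt_m, inv_sqrt_m)
    d = 0.5 * (d + d.T)
    evals, evecs = np.linalg.eigh(d)
    scale = max(float(evals.max()), 0.0) or 1.0
    if evals.min() < -check_tol * scale:
        raise ValueError(
            f"negative Hessian eigenvalue {evals.min():.3e} beyond tolerance: "
            "system is not at a potential-energy minimum"
        )
    evals = np.clip(evals, 0.0, None)
    freqs = np.sqrt(evals) / (2.0 * np.pi)
    cart = (evecs.T * inv_sqrt_m[None, :]).reshape(evals.size, n, 3)
    return ModeSet(atoms=system.atoms, mode_frequencies=freqs, eigenvectors=cart)


def synth_hydrated_variant(
    core: HarmonicSystem,
    n_shell_particles: int,
    attach_stiffness: float,
    seed: int = 0,
    shell_mass_amu: float = 18.0,
    shell_charge_e: float = -0.2,
    shell_distance: float = 0.12,
    n_attachments: int = 6,
) -> HarmonicSystem:
    """Attach ``water``-labelled shell particles to the core by stiff springs.

    Each shell particle sits ``shell_distance`` nm outside a core atom and is
    tied to its ``n_attachments`` nearest core atoms (at least three
    non-collinear attachments, so the particle adds no floppy modes of its
    own; more attachments bridge separated core atoms and stiffen the core's
    soft collective modes, the mechanism behind the hydration blue-shift).
    """
    if attach_stiffness <= 0:
        raise ValueError("attach_stiffness must be positive")
    rng = np.random.default_rng(seed)
    core_coords = core.atoms.coordinates
    if core_coords is None:
        raise ValueError("core system has no coordinates")
    n_core = core.n_atoms
    centroid = core_coords.mean(axis=0)

    shell_coords = np.empty((n_shell_particles, 3))
    for s in range(n_shell_particles):
        anchor = core_coords[rng.integers(n_core)]
        out = anchor - centroid
        norm = np.linalg.norm(out)
        direction = out / norm if norm > 1e-12 else rng.standard_normal(3)
        direction = direction + 0.3 * rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        shell_coords[s] = anchor + shell_distance * direction

    coords = np.vstack([core_coords, shell_coords])
    springs = [tuple(row) for row in core.springs]
    n_attach = min(max(3, n_attachments), n_core)
    for s in range(n_shell_particles):
        d = np.linalg.norm(core_coords - shell_coords[s], axis=1)
        for j in np.argsort(d)[:n_attach]:
            springs.append(
                (n_core + s, int(j), attach_stiffness, float(d[j]))
            )
    springs_arr = np.array(springs, dtype=float)

    atoms = AtomSet(
        masses=np.concatenate(
            [core.atoms.masses, np.full(n_shell_particles, shell_mass_amu * ATOMIC_MASS)]
        ),
        charges=np.concatenate(
            [
                core.atoms.charges,
                np.full(n_shell_particles, shell_charge_e * ELEMENTARY_CHARGE),
            ]
        ),
        component_labels=np.concatenate(
            [core.atoms.component_labels, np.full(n_shell_particles, "water", dtype=object)]
        ),
        residue_indices=np.concatenate(
            [
                core.atoms.residue_indices,
                core.atoms.residue_indices.max() + 1 + np.arange(n_shell_particles),
            ]
        ),
        coordinates=coords,
    )
    return HarmonicSystem(
        atoms=atoms, springs=springs_arr, hessian=_pairwise_hessian(coords, springs_arr)
    )


def synth_mode_ensemble(
    n_replicas: int,
    topology: str = "random",
    n_atoms: int = 10,
    charges_e=None,
    spring_constant: float = 0.1,
    seed: int = 0,
    **kwargs,
) -> ModeEnsemble:
    """Solve modes of ``n_replicas`` seed-jittered systems as an ensemble.

    Replica r is built with seed ``seed + 1000*r``; charges default to a
    deterministic alternating pattern so dipole derivatives are non-trivial.
    """
    if charges_e is None:
        charges_e = 0.3 * (-1.0) ** np.arange(n_atoms)
    replicas = []
    for r in range(n_replicas):
        system = build_harmonic_system(
            topology,
            n_atoms,
            charges_e=charges_e,
            spring_constant=spring_constant,
            seed=seed + 1000 * r,
            **kwargs,
        )
        replicas.append(solve_modes(system))
    return ModeEnsemble(replicas=tuple(replicas))


def synth_shell_trajectory(
    n_waters: int,
    stay_probability: float,
    n_frames: int,
    boundaries=(0.0, 3.0, 5.0, 7.0, 9.0),
    frame_spacing_ps: float = 20.0,
    seed: int = 0,
) -> ShellTrajectory:
    """First-order Markov chain per water over the shells of ``boundaries``.

    Each frame a water stays in its current shell with probability
    ``stay_probability`` and otherwise jumps uniformly to one of the other
    shells.  Initial shells are uniform.  Deterministic for a fixed seed.
    """
    p = float(stay_probability)
    if not 0.0 <= p <= 1.0:
        raise ValueError("stay_probability must be in [0, 1]")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2 (persistence undefined otherwise)")
    bounds = np.asarray(boundaries, dtype=float)
    n_shells = bounds.size - 1
    if n_shells < 2 and p < 1.0:
        raise ValueError("need at least 2 shells for jumps")
    rng = np.random.default_rng(seed)
    idx = np.empty((n_frames, n_waters), dtype=int)
    idx[0] = rng.integers(0, n_shells, size=n_waters)
    for f in range(1, n_frames):
        stay = rng.random(n_waters) < p
        jump_to = rng.integers(0, n_shells - 1, size=n_waters)
        # shift so the draw never lands on the current shell
        jump_to = jump_to + (jump_to >= idx[f - 1])
        idx[f] = np.where(stay, idx[f - 1], jump_to)
    return ShellTrajectory(
        shell_index=idx, frame_spacing_ps=float(frame_spacing_ps), boundaries=bounds
    )
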