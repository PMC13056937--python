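"""Lorentz-oscillator dielectric response on a frequency grid.

Each vibrational mode l (frequency nu_l, dipole-variation magnitude rho_l)
contributes a damped-oscillator term to the complex susceptibility of a
dilute isotropic ensemble of N_V molecules per m^3:

    chi(nu) = (1/3) * N_V / (4 pi^2 eps0) * sum_l rho_l^2
              / (nu_l^2 - nu^2 - j nu gamma_l)

Real/imaginary parts follow with A_l = nu_l^2 - nu^2 and B_l = nu gamma_l:
chi' carries A_l in the numerator, chi'' carries B_l, both over A_l^2 + B_l^2
with prefactor N_V / (12 pi^2 eps0).  The relative permittivity is
eps' = 1 + eps_inf + chi', eps'' = chi''; the extinction coefficient k comes
from n + jk = sqrt(eps), and the absorption coefficient is
alpha = 4 pi nu k / c.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import AVOGADRO, EPSILON_0, SPEED_OF_LIGHT
from .dipoles import DipoleTable

__all__ = [
    "LorentzParams",
    "DielectricSpectrum",
    "number_density_from_molarity",
    "susceptibility",
    "susceptibility_complex",
    "permittivity_extinction_absorption",
    "extinction_from_permittivity",
    "dielectric_spectrum",
    "ensemble_average_spectra",
    "sweep",
    "static_susceptibility",
    "kramers_kronig_chi_real",
    "weak_loss_absorption",
    "default_grid",
]

#: Fixed orientational-averaging factor for an isotropic dilute ensemble.
ORIENTATION_FACTOR = 1.0 / 3.0


@dataclass(frozen=True)
class LorentzParams:
    """Damping, number density and high-frequency baseline for the model.

    ``gamma`` (Hz) is a single phenomenological damping rate applied
    uniformly to all modes; pass ``gamma_per_mode`` for mode-resolved
    damping.  ``eps_infinity`` is an additive offset to eps' only (electronic
    polarization baseline; 0 by default, ~2 for organic media).
    """

    gamma: float
    number_density: float
    eps_infinity: float = 0.0
    gamma_per_mode: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.number_density < 0:
            raise ValueError("number_density must be non-negative")
        if self.eps_infinity < 0:
            raise ValueError("eps_infinity must be non-negative")
        if self.gamma_per_mode is not None:
            g = np.asarray(self.gamma_per_mode, dtype=float)
            if np.any(g <= 0):
                raise ValueError("per-mode gamma values must be positive")
            object.__setattr__(self, "gamma_per_mode", g)


@dataclass(frozen=True)
class DielectricSpectrum:
    """Complex susceptibility, permittivity, extinction and absorption."""

    grid: np.ndarray  # Hz
    chi_real: np.ndarray
    chi_imag: np.ndarray
    eps_real: np.ndarray
    eps_imag: np.ndarray
    extinction: np.ndarray
    absorption: np.ndarray  # 1/m
    sd: dict = field(default_factory=dict)  # ensemble sd per field name


def number_density_from_molarity(concentration_mol_l: float) -> float:
    """mol/L -> molecules/m^3 via Avogadro's number."""
    if concentration_mol_l < 0:
        raise ValueError("concentration must be non-negative")
    return concentration_mol_l * 1000.0 * AVOGADRO


def default_grid() -> np.ndarray:
    """1-2000 GHz in 1 GHz steps."""
    return np.arange(1.0, 2001.0) * 1e9


def _check_mode_frequencies(dipoles: DipoleTable) -> None:
    if np.any(dipoles.mode_frequencies <= 0):
        raise ValueError(
            "all mode frequencies must be positive (remove rigid-body modes "
            "before evaluating the susceptibility)"
        )


def _gammas(dipoles: DipoleTable, params: LorentzParams) -> np.ndarray:
    if params.gamma_per_mode is not None:
        if params.gamma_per_mode.size != dipoles.n_modes:
            raise ValueError("gamma_per_mode length must equal mode count")
        return params.gamma_per_mode
    return np.full(dipoles.n_modes, params.gamma)


def susceptibility(
    dipoles: DipoleTable, params: LorentzParams, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """chi'(nu), chi''(nu) by the split real/imaginary evaluation."""
    _check_mode_frequencies(dipoles)
    nu = np.asarray(grid, dtype=float)
    if np.any(nu < 0):
        raise ValueError("grid frequencies must be non-negative")
    gam = _gammas(dipoles, params)
    pref = params.number_density / (12.0 * np.pi**2 * EPSILON_0)
    rho2 = dipoles.magnitudes**2
    a = dipoles.mode_frequencies[:, None] ** 2 - nu[None, :] ** 2  # (M, K)
    b = nu[None, :] * gam[:, None]
    denom = a**2 + b**2
    chi_real = pref * np.sum(rho2[:, None] * a / denom, axis=0)
    chi_imag = pref * np.sum(rho2[:, None] * b / denom, axis=0)
    if dipoles.n_modes == 0:
        chi_real = np.zeros_like(nu)
        chi_imag = np.zeros_like(nu)
    return chi_real, chi_imag


def susceptibility_complex(
    dipoles: DipoleTable, params: LorentzParams, grid: np.ndarray
) -> np.ndarray:
    """chi(nu) evaluated in complex arithmetic (cross-check of the split form)."""
    _check_mode_frequencies(dipoles)
    nu = np.asarray(grid, dtype=float)
    gam = _gammas(dipoles, params)
    pref = ORIENTATION_FACTOR * params.number_density / (4.0 * np.pi**2 * EPSILON_0)
    denom = (
        dipoles.mode_frequencies[:, None] ** 2
        - nu[None, :] ** 2
        - 1j * nu[None, :] * gam[:, None]
    )
    chi = pref * np.sum(dipoles.magnitudes[:, None] ** 2 / denom, axis=0)
    if dipoles.n_modes == 0:
        chi = np.zeros(nu.shape, dtype=complex)
    # 1/(A - jB) = (A + jB)/(A^2 + B^2): chi'' = +Im chi with this convention
    return chi


def static_susceptibility(dipoles: DipoleTable, params: LorentzParams) -> float:
    """Closed-form chi'(0) = pref * sum rho_l^2 / nu_l^2."""
    _check_mode_frequencies(dipoles)
    pref = params.number_density / (12.0 * np.pi**2 * EPSILON_0)
    return float(pref * np.sum(dipoles.magnitudes**2 / dipoles.mode_frequencies**2))


def extinction_from_permittivity(
    eps_real: np.ndarray, eps_imag: np.ndarray
) -> np.ndarray:
    """k = sqrt((-eps' + sqrt(eps'^2 + eps''^2)) / 2); defined for all real inputs."""
    eps_real = np.asarray(eps_real, dtype=float)
    eps_imag = np.asarray(eps_imag, dtype=float)
    mag = np.hypot(eps_real, eps_imag)
    # for eps' > 0 the direct form cancels catastrophically at weak loss;
    # use (mag - eps')/2 = eps''^2 / (2 (mag + eps')) there
    with np.errstate(divide="ignore", invalid="ignore"):
        stable = eps_imag**2 / (2.0 * (mag + eps_real))
    direct = 0.5 * (mag - eps_real)
    arg = np.where(eps_real > 0, np.where(mag + eps_real > 0, stable, 0.0), direct)
    return np.sqrt(np.clip(arg, 0.0, None))


def permittivity_extinction_absorption(
    grid: np.ndarray,
    chi_real: np.ndarray,
    chi_imag: np.ndarray,
    params: LorentzParams,
) -> DielectricSpectrum:
    """Assemble the full spectrum from susceptibility on a grid.

    eps' = 1 + eps_infinity + chi', eps'' = chi''; alpha = 4 pi nu k / c with
    alpha(0) forced to 0.
    """
    nu = np.asarray(grid, dtype=float)
    eps_real = 1.0 + params.eps_infinity + np.asarray(chi_real, dtype=float)
    eps_imag = np.asarray(chi_imag, dtype=float)
    k = extinction_from_permittivity(eps_real, eps_imag)
    alpha = 4.0 * np.pi * nu * k / SPEED_OF_LIGHT
    alpha = np.where(nu == 0.0, 0.0, alpha)
    return DielectricSpectrum(
        grid=nu,
        chi_real=np.asarray(chi_real, dtype=float),
        chi_imag=eps_imag.copy(),
        eps_real=eps_real,
        eps_imag=eps_imag,
        extinction=k,
        absorption=alpha,
    )


def weak_loss_absorption(spectrum: DielectricSpectrum) -> np.ndarray:
    """Weak-loss approximation alpha ~ (2 pi nu / c) eps'' / sqrt(eps')."""
    return (
        2.0
        * np.pi
        * spectrum.grid
        / SPEED_OF_LIGHT
        * spectrum.eps_imag
        / np.sqrt(spectrum.eps_real)
    )


def dielectric_spectrum(
    dipoles: DipoleTable, params: LorentzParams, grid: np.ndarray
) -> DielectricSpectrum:
    """Susceptibility plus derived quantities in one call."""
    chi_real, chi_imag = susceptibility(dipoles, params, grid)
    return permittivity_extinction_absorption(grid, chi_real, chi_imag, params)


_FIELDS = ("chi_real", "chi_imag", "eps_real", "eps_imag", "extinction", "absorption")


def ensemble_average_spectra(spectra: list[DielectricSpectrum]) -> DielectricSpectrum:
    """Point-wise mean (and sd) of every derived quantity independently.

    All quantities — chi-level and alpha-level — are averaged separately, so
    both readings of "average of the spectra" are available in the output.
    """
    if not spectra:
        raise ValueError("no spectra to average")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid.shape != grid.shape or not np.array_equal(s.grid, grid):
            raise ValueError("spectra grids differ; cannot average")
    means, sds = {}, {}
    for name in _FIELDS:
        stack = np.stack([getattr(s, name) for s in spectra])
        means[name] = stack.mean(axis=0)
        sds[name] = stack.std(axis=0, ddof=1) if len(spectra) > 1 else np.zeros_like(grid)
    return DielectricSpectrum(grid=grid.copy(), sd=sds, **means)


def sweep(
    dipoles: DipoleTable | list[DipoleTable],
    gammas: list[float],
    concentrations_mol_l: list[float],
    grid: np.ndarray,
    eps_infinity: float = 0.0,
) -> dict[tuple[float, float], DielectricSpectrum]:
    """One spectrum per (gamma, concentration) combination.

    A list of dipole tables (one per replica) is ensemble-averaged per
    combination.  Keys are (gamma_Hz, concentration_mol_L).
    """
    if not gammas or not concentrations_mol_l:
        raise ValueError("gamma and concentration lists must be nonempty")
    tables = dipoles if isinstance(dipoles, list) else [dipoles]
    out = {}
    for gamma in gammas:
        for conc in concentrations_mol_l:
            if conc < 0:
                raise ValueError("concentration must be non-negative")
            params = LorentzParams(
                gamma=gamma,
                number_density=number_density_from_molarity(conc),
                eps_infinity=eps_infinity,
            )
            per_replica = [dielectric_spectrum(t, params, grid) for t in tables]
            out[(gamma, conc)] = (
                per_replica[0]
                if len(per_replica) == 1
                else ensemble_average_spectra(per_replica)
            )
    return out


def kramers_kronig_chi_real(
    grid: np.ndarray, chi_imag: np.ndarray, nu_eval: float
) -> float:
    """Reconstruct chi'(nu_eval) from chi'' via the principal-value integral.

    chi'(nu) = (2/pi) P int nu' chi''(nu') / (nu'^2 - nu^2) dnu' over
    [grid[0], grid[-1]].  The pole at nu' = nu is handled by subtracting
    chi''(nu) analytically; validates the Lorentz numerics, not a production
    transform.
    """
    nu = float(nu_eval)
    x = np.asarray(grid, dtype=float)
    y = np.asarray(chi_imag, dtype=float)
    if not (x[0] < nu < x[-1]):
        raise ValueError("nu_eval must lie strictly inside the grid")
    y_at = np.interp(nu, x, y)
    # split 2 nu'/(nu'^2 - nu^2) = 1/(nu' - nu) + 1/(nu' + nu)
    with np.errstate(divide="ignore", invalid="ignore"):
        singular = np.where(x != nu, (y - y_at) / (x - nu), 0.0)
    # fill the removable singularity with a local slope estimate
    if np.any(x == nu):
        i = int(np.argmax(x == nu))
        lo, hi = max(i - 1, 0), min(i + 1, x.size - 1)
        singular[i] = (y[hi] - y[lo]) / (x[hi] - x[lo])
    part1 = np.trapezoid(singular, x) + y_at * np.log((x[-1] - nu) / (nu - x[0]))
    part2 = np.trapezoid(y / (x + nu), x)
    return float((part1 + part2) / np.pi)
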