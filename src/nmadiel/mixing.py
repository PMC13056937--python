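"""Bound-water accounting and dilute linear-mixing corrections.

A protein at molar concentration c sequesters n_b waters per molecule in its
hydration shell; those waters are dynamically restricted and lost to the
bulk sub-THz response.  The removed-water fraction
f_rm = n_b * c / c_water (c_water the bulk-water molarity, ~55.35 mol/L)
then reduces the water contribution to chi', chi'' and alpha approximately
in proportion, which this module evaluates with caller-supplied water
permittivity values (no water model is bundled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import AVOGADRO, SPEED_OF_LIGHT, WATER_MOLARITY
from .spectra import extinction_from_permittivity

__all__ = [
    "MixingEstimate",
    "removed_water_fraction",
    "dilute_mixing_deltas",
    "concentration_conversions",
    "shell_overlap_threshold",
    "estimate_mixing",
]


@dataclass(frozen=True)
class MixingEstimate:
    """Bound-water mixing summary at one probe frequency."""

    n_b: float
    concentration_mol_l: float
    f_rm: float
    probe_frequency_hz: float
    water_eps: tuple[float, float]  # (eps'_w, eps''_w) at the probe frequency
    delta_chi_real: float
    delta_chi_imag: float
    delta_alpha: float  # 1/m
    water_molarity: float = WATER_MOLARITY


def removed_water_fraction(
    n_b: float, concentration_mol_l: float, water_molarity: float = WATER_MOLARITY
) -> float:
    """f_rm = n_b * c / c_water (dimensionless fraction, must be <= 1)."""
    if n_b < 0 or concentration_mol_l < 0:
        raise ValueError("n_b and concentration must be non-negative")
    f_rm = n_b * concentration_mol_l / water_molarity
    if f_rm > 1.0:
        raise ValueError(
            f"f_rm = {f_rm:.3g} > 1: more bound water than water present "
            "(unphysical concentration)"
        )
    return f_rm


def _alpha_from_eps(eps_real: float, eps_imag: float, nu: float) -> float:
    k = extinction_from_permittivity(eps_real, eps_imag)
    return float(4.0 * np.pi * nu * k / SPEED_OF_LIGHT)


def dilute_mixing_deltas(
    f_rm: float,
    water_eps: tuple[float, float],
    probe_frequency_hz: float,
) -> tuple[float, float, float]:
    """(delta_chi', delta_chi'', delta_alpha) for removed-water fraction f_rm.

    delta_chi' = -f_rm (eps'_w - 1); delta_chi'' = -f_rm eps''_w;
    delta_alpha is the change in the absorption coefficient when the water
    permittivity is reduced by those deltas, via the extinction relation.
    """
    if water_eps is None:
        raise ValueError("water permittivity values are required (none bundled)")
    eps_w_real, eps_w_imag = float(water_eps[0]), float(water_eps[1])
    delta_chi_real = -f_rm * (eps_w_real - 1.0)
    delta_chi_imag = -f_rm * eps_w_imag
    alpha_base = _alpha_from_eps(eps_w_real, eps_w_imag, probe_frequency_hz)
    alpha_adj = _alpha_from_eps(
        eps_w_real + delta_chi_real, eps_w_imag + delta_chi_imag, probe_frequency_hz
    )
    return delta_chi_real, delta_chi_imag, alpha_adj - alpha_base


def concentration_conversions(
    concentration_mol_l: float, molar_mass_kg_mol: float
) -> tuple[float, float]:
    """(mass concentration mg/mL, number density m^-3) from molarity.

    mol/L * kg/mol = kg/L = g/mL; N_V = c * 1000 * N_A.
    """
    if concentration_mol_l < 0 or molar_mass_kg_mol < 0:
        raise ValueError("inputs must be non-negative")
    mass_mg_ml = concentration_mol_l * molar_mass_kg_mol * 1000.0
    n_v = concentration_mol_l * 1000.0 * AVOGADRO
    return mass_mg_ml, n_v


def shell_overlap_threshold(
    protein_effective_radius_nm: float,
    shell_thickness_angstrom: float,
    molar_mass_kg_mol: float,
) -> float:
    """Mass concentration (g/mL) at which hydration-shell spheres fill space.

    The per-molecule volume 1/N_V equals the volume of a sphere of radius
    (protein radius + shell thickness); simple sphere volumes, no
    packing-fraction correction.
    """
    if protein_effective_radius_nm <= 0:
        raise ValueError("protein radius must be positive")
    radius_m = protein_effective_radius_nm * 1e-9 + shell_thickness_angstrom * 1e-10
    volume = 4.0 / 3.0 * np.pi * radius_m**3
    n_v = 1.0 / volume
    mass_kg_m3 = n_v / AVOGADRO * molar_mass_kg_mol
    return mass_kg_m3 / 1000.0  # kg/m^3 -> g/mL


def estimate_mixing(
    n_b: float,
    concentration_mol_l: float,
    water_eps: tuple[float, float],
    probe_frequency_hz: float,
    water_molarity: float = WATER_MOLARITY,
) -> MixingEstimate:
    """Full bound-water accounting at one probe frequency."""
    f_rm = removed_water_fraction(n_b, concentration_mol_l, water_molarity)
    d_re, d_im, d_alpha = dilute_mixing_deltas(f_rm, water_eps, probe_frequency_hz)
    return MixingEstimate(
        n_b=n_b,
        concentration_mol_l=concentration_mol_l,
        f_rm=f_rm,
        probe_frequency_hz=probe_frequency_hz,
        water_eps=(float(water_eps[0]), float(water_eps[1])),
        delta_chi_real=d_re,
        delta_chi_imag=d_im,
        delta_alpha=d_alpha,
        water_molarity=water_molarity,
    )
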