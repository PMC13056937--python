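import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nmadiel as nd
from nmadiel.constants import EPSILON_0, SPEED_OF_LIGHT
from nmadiel.dipoles import DipoleTable, mode_dipole
from nmadiel.spectra import (
    LorentzParams,
    dielectric_spectrum,
    ensemble_average_spectra,
    extinction_from_permittivity,
    kramers_kronig_chi_real,
    number_density_from_molarity,
    permittivity_extinction_absorption,
    static_susceptibility,
    susceptibility,
    susceptibility_complex,
    sweep,
    weak_loss_absorption,
)


def single_mode_table(nu_l=1e11, rho=1e-21):
    return DipoleTable(
        component="whole",
        vectors=np.array([[rho, 0.0, 0.0]]),
        magnitudes=np.array([rho]),
        mode_frequencies=np.array([nu_l]),
    )


PARAMS = LorentzParams(gamma=1e10, number_density=3.011e23)


class TestSusceptibility:
    def test_empty_sum_is_zero(self):
        empty = DipoleTable(
            component="whole",
            vectors=np.empty((0, 3)),
            magnitudes=np.empty(0),
            mode_frequencies=np.empty(0),
        )
        grid = np.array([1e9, 1e11])
        chi_re, chi_im = susceptibility(empty, PARAMS, grid)
        np.testing.assert_array_equal(chi_re, 0.0)
        np.testing.assert_array_equal(chi_im, 0.0)

    def test_on_resonance_real_part_vanishes(self):
        table = single_mode_table(nu_l=1e11)
        chi_re, _ = susceptibility(table, PARAMS, np.array([1e11]))
        assert chi_re[0] == 0.0

    def test_on_resonance_imag_closed_form(self):
        # frozen from a 50-digit complex evaluation of the Lorentz sum at
        # nu = nu_l with N_V = 3.011e23, rho = 1e-21, nu_l = 100 GHz,
        # gamma = 10 GHz
        table = single_mode_table(nu_l=1e11, rho=1e-21)
        _, chi_im = susceptibility(table, PARAMS, np.array([1e11]))
        assert chi_im[0] == pytest.approx(2.8713162855551514e-31, rel=1e-12)
        closed = PARAMS.number_density * 1e-42 / (
            12.0 * np.pi**2 * EPSILON_0 * 1e11 * 1e10
        )
        assert chi_im[0] == pytest.approx(closed, rel=1e-12)

    def test_rigid_mode_is_error(self):
        table = DipoleTable(
            component="whole",
            vectors=np.array([[1e-21, 0.0, 0.0]]),
            magnitudes=np.array([1e-21]),
            mode_frequencies=np.array([0.0]),
        )
        with pytest.raises(ValueError, match="rigid"):
            susceptibility(table, PARAMS, np.array([1e9]))

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError):
            LorentzParams(gamma=0.0, number_density=1.0)

    def test_complex_vs_split_equivalence(self, random_modes):
        table = mode_dipole(random_modes)
        grid = np.linspace(1e9, 2e12, 400)
        chi_re, chi_im = susceptibility(table, PARAMS, grid)
        chi = susceptibility_complex(table, PARAMS, grid)
        np.testing.assert_allclose(chi.real, chi_re, rtol=1e-12)
        np.testing.assert_allclose(chi.imag, chi_im, rtol=1e-12)

    def test_static_limit_closed_form(self, random_modes):
        table = mode_dipole(random_modes)
        chi_re, _ = susceptibility(table, PARAMS, np.array([0.0]))
        assert chi_re[0] == pytest.approx(
            static_susceptibility(table, PARAMS), rel=1e-12
        )

    def test_high_frequency_decay(self, random_modes):
        table = mode_dipole(random_modes)
        nu_max = table.mode_frequencies.max()
        grid = np.array([10.0 * nu_max, 20.0 * nu_max])
        chi = susceptibility_complex(table, PARAMS, grid)
        # |chi| <= C / nu^2 with C = pref * sum rho^2 fixed by the sum rule
        pref = PARAMS.number_density / (12.0 * np.pi**2 * EPSILON_0)
        c_bound = pref * np.sum(table.magnitudes**2)
        assert np.all(np.abs(chi) <= 1.02 * c_bound / grid**2)

    def test_positivity_of_loss(self, random_modes):
        table = mode_dipole(random_modes)
        grid = np.linspace(1e9, 3e12, 500)
        _, chi_im = susceptibility(table, PARAMS, grid)
        assert np.all(chi_im > 0.0)

    @given(st.floats(min_value=1e9, max_value=1e13))
    @settings(max_examples=30, deadline=None)
    def test_positivity_property(self, nu):
        table = single_mode_table(nu_l=2e11, rho=1e-20)
        _, chi_im = susceptibility(table, PARAMS, np.array([nu]))
        assert chi_im[0] > 0.0

    def test_kramers_kronig_reconstruction(self):
        nu_l = 1e11
        table = single_mode_table(nu_l=nu_l, rho=1e-20)
        grid = np.linspace(0.01 * nu_l, 100.0 * nu_l, 400_000)
        chi_re, chi_im = susceptibility(table, PARAMS, grid)
        for nu_eval in (0.5 * nu_l, 2.0 * nu_l):
            expected = susceptibility(table, PARAMS, np.array([nu_eval]))[0][0]
            reconstructed = kramers_kronig_chi_real(grid, chi_im, nu_eval)
            assert reconstructed == pytest.approx(expected, rel=0.02)


class TestPermittivityExtinctionAbsorption:
    def test_lossless_medium(self):
        k = extinction_from_permittivity(np.array([1.0]), np.array([0.0]))
        assert k[0] == 0.0

    def test_hand_evaluated_3_4(self):
        k = extinction_from_permittivity(np.array([3.0]), np.array([4.0]))
        assert k[0] == pytest.approx(1.0, rel=1e-14)

    def test_hand_evaluated_0_2_and_alpha(self):
        k = extinction_from_permittivity(np.array([0.0]), np.array([2.0]))
        assert k[0] == pytest.approx(1.0, rel=1e-14)
        nu = SPEED_OF_LIGHT / (4.0 * np.pi)
        params = LorentzParams(gamma=1e10, number_density=0.0)
        spectrum = permittivity_extinction_absorption(
            np.array([nu]), np.array([-1.0]), np.array([2.0]), params
        )
        assert spectrum.absorption[0] == pytest.approx(1.0, rel=1e-12)

    def test_alpha_zero_at_zero_frequency(self):
        params = LorentzParams(gamma=1e10, number_density=0.0)
        spectrum = permittivity_extinction_absorption(
            np.array([0.0]), np.array([5.0]), np.array([5.0]), params
        )
        assert spectrum.absorption[0] == 0.0

    def test_eps_infinity_offset(self):
        params = LorentzParams(gamma=1e10, number_density=0.0, eps_infinity=2.0)
        spectrum = permittivity_extinction_absorption(
            np.array([1e11]), np.array([0.25]), np.array([0.1]), params
        )
        assert spectrum.eps_real[0] == pytest.approx(3.25)
        assert spectrum.eps_imag[0] == pytest.approx(0.1)

    def test_weak_loss_approximation(self, random_modes):
        table = mode_dipole(random_modes)
        params = LorentzParams(gamma=1e12, number_density=3.011e20)
        grid = np.linspace(1e10, 4e11, 50)
        spectrum = dielectric_spectrum(table, params, grid)
        assert np.max(spectrum.eps_imag / spectrum.eps_real) < 0.01
        np.testing.assert_allclose(
            spectrum.absorption, weak_loss_absorption(spectrum), rtol=1e-4
        )


class TestEnsembleAverage:
    def test_single_spectrum_identity(self, random_modes):
        spectrum = dielectric_spectrum(
            mode_dipole(random_modes), PARAMS, np.linspace(1e9, 1e12, 50)
        )
        avg = ensemble_average_spectra([spectrum])
        np.testing.assert_array_equal(avg.absorption, spectrum.absorption)
        np.testing.assert_array_equal(avg.sd["absorption"], 0.0)

    def test_two_identical_spectra(self, random_modes):
        spectrum = dielectric_spectrum(
            mode_dipole(random_modes), PARAMS, np.linspace(1e9, 1e12, 50)
        )
        avg = ensemble_average_spectra([spectrum, spectrum])
        np.testing.assert_allclose(avg.chi_imag, spectrum.chi_imag)
        np.testing.assert_allclose(avg.sd["chi_imag"], 0.0, atol=1e-30)

    def test_jittered_replicas_match_brute_force(self):
        rng = np.random.default_rng(3)
        grid = np.linspace(1e9, 1e12, 200)
        probe = 123
        spectra, alphas = [], []
        for _ in range(10):
            nu_l = 1e11 * (1.0 + 0.1 * rng.standard_normal())
            table = single_mode_table(nu_l=abs(nu_l), rho=1e-20)
            s = dielectric_spectrum(table, PARAMS, grid)
            spectra.append(s)
            alphas.append(s.absorption[probe])
        avg = ensemble_average_spectra(spectra)
        assert avg.absorption[probe] == pytest.approx(np.mean(alphas), rel=1e-12)

    def test_grid_mismatch_rejected(self, random_modes):
        table = mode_dipole(random_modes)
        a = dielectric_spectrum(table, PARAMS, np.linspace(1e9, 1e12, 50))
        b = dielectric_spectrum(table, PARAMS, np.linspace(1e9, 1e12, 60))
        with pytest.raises(ValueError):
            ensemble_average_spectra([a, b])


class TestSweep:
    def test_chi_linear_in_concentration(self, random_modes):
        table = mode_dipole(random_modes)
        grid = np.linspace(1e9, 1e12, 100)
        out = sweep(table, [1e10], [0.5e-3, 1.0e-3], grid)
        chi1 = out[(1e10, 0.5e-3)].chi_imag
        chi2 = out[(1e10, 1.0e-3)].chi_imag
        np.testing.assert_allclose(chi2, 2.0 * chi1, rtol=1e-12)

    def test_doubling_gamma_halves_on_resonance_loss(self):
        table = single_mode_table(nu_l=1e11, rho=1e-20)
        grid = np.array([1e11])
        out = sweep(table, [1e10, 2e10], [0.5e-3], grid)
        chi_a = out[(1e10, 0.5e-3)].chi_imag[0]
        chi_b = out[(2e10, 0.5e-3)].chi_imag[0]
        assert chi_b == pytest.approx(0.5 * chi_a, rel=1e-12)

    def test_dilute_alpha_nearly_linear(self, random_modes):
        table = mode_dipole(random_modes)
        grid = np.linspace(1e10, 1e12, 100)
        c = 1e-8  # dilute enough that max chi' << 0.01
        out = sweep(table, [1e10], [c, 2.0 * c], grid)
        s1, s2 = out[(1e10, c)], out[(1e10, 2.0 * c)]
        assert s1.chi_real.max() < 0.01
        dev = np.abs(s2.absorption - 2.0 * s1.absorption) / s2.absorption.max()
        assert dev.max() < 0.01

    def test_negative_concentration_rejected(self, random_modes):
        with pytest.raises(ValueError):
            sweep(mode_dipole(random_modes), [1e10], [-1e-3], np.array([1e10]))

    def test_empty_lists_rejected(self, random_modes):
        with pytest.raises(ValueError):
            sweep(mode_dipole(random_modes), [], [1e-3], np.array([1e10]))

    def test_number_density_conversion(self):
        assert number_density_from_molarity(0.5e-3) == pytest.approx(
            3.011e23, rel=1e-4
        )


def test_hydration_blue_shift_in_absorption(hydrated_pair):
    """Stiff shell shifts the lowest absorption feature upward in frequency."""
    bare, hydrated = hydrated_pair
    grid = np.linspace(1e9, 2e12, 4000)
    params = LorentzParams(gamma=5e9, number_density=3.011e23)

    def lowest_feature(modeset):
        spectrum = dielectric_spectrum(mode_dipole(modeset), params, grid)
        alpha = spectrum.absorption
        interior = (alpha[1:-1] > alpha[:-2]) & (alpha[1:-1] > alpha[2:])
        peaks = np.nonzero(interior)[0] + 1
        assert peaks.size > 0
        return grid[peaks[0]]

    assert lowest_feature(hydrated) >= lowest_feature(bare)
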