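"""Scattering: Debye profiles, Guinier analysis, chi-square, decompositions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clampscope import (
    FormFactorTable,
    ScatteringProfile,
    build_helix_bundle,
    chi2_compare,
    coordinate_rg,
    debye_profile,
    guinier_fit,
    nstate_fit,
    rg_mix,
    two_state_fit,
)
from clampscope._linalg import rotation_about_axis
from clampscope.saxs import RgMixInputs, default_q_grid, read_profile, write_profile
from clampscope.synthetic import MixtureSpec, simulate_mixture_profile

from conftest import make_point_model


class TestFormFactors:
    @pytest.mark.parametrize("element,electrons", [
        ("H", 1), ("C", 6), ("N", 7), ("O", 8), ("P", 15), ("S", 16),
    ])
    def test_forward_scattering_equals_electron_count(self, element, electrons):
        assert FormFactorTable().f0(element) == pytest.approx(electrons, abs=0.1)

    def test_excluded_volume_reduces_forward_scattering(self):
        table = FormFactorTable()
        q = np.array([0.0, 0.1])
        vac = table.factor("C", q, "vacuum")
        exv = table.factor("C", q, "excluded_volume")
        assert np.all(exv < vac)


class TestDebyeProfile:
    def test_single_atom_is_squared_form_factor(self, q_grid):
        table = FormFactorTable()
        prof = debye_profile(make_point_model([(0, 0, 0)]), q_grid, table)
        np.testing.assert_allclose(prof.intensity, table.factor("C", q_grid) ** 2,
                                   rtol=1e-12)
        assert prof.intensity[0] == pytest.approx(36.0, abs=0.2)

    def test_two_point_scatterers_closed_form(self, q_grid):
        table = FormFactorTable()
        prof = debye_profile(make_point_model([(0, 0, 0), (10.0, 0, 0)]), q_grid, table)
        f = table.factor("C", q_grid)
        with np.errstate(invalid="ignore"):
            sinc = np.where(q_grid > 0, np.sin(10 * q_grid) / (10 * q_grid), 1.0)
        np.testing.assert_allclose(prof.intensity, 2 * f ** 2 * (1 + sinc), rtol=1e-12)

    def test_matches_literal_double_sum_oracle(self, q_grid):
        rng = np.random.default_rng(42)
        coords = rng.uniform(-15, 15, size=(50, 3))
        elements = rng.choice(["C", "N", "O", "P"], size=50)
        model = make_point_model(coords, element="C")
        for atom, el in zip(model.chains["A"][0].atoms, elements):
            atom.element = el
        table = FormFactorTable()
        prof = debye_profile(model, q_grid, table)
        # independent oracle: literal O(N^2) double loop
        factors = {el: table.factor(el, q_grid) for el in set(elements)}
        oracle = np.zeros_like(q_grid)
        for i in range(50):
            for j in range(50):
                r = np.linalg.norm(coords[i] - coords[j])
                with np.errstate(invalid="ignore"):
                    sinc = np.where(q_grid * r > 0, np.sin(q_grid * r) / (q_grid * r), 1.0)
                oracle += factors[elements[i]] * factors[elements[j]] * sinc
        np.testing.assert_allclose(prof.intensity, oracle, rtol=1e-10)

    def test_rigid_motion_invariance(self, q_grid, bundle_compact):
        base = debye_profile(bundle_compact, q_grid)
        moved = bundle_compact.copy()
        R = rotation_about_axis([1.0, -2.0, 0.5], 1.1)
        t = np.array([5.0, -3.0, 8.0])
        for _, _, atom in moved.iter_atoms():
            atom.coordinates = R @ atom.coordinates + t
        prof = debye_profile(moved, q_grid)
        np.testing.assert_allclose(prof.intensity, base.intensity, rtol=1e-9)

    def test_unknown_elements_only_raises(self, q_grid):
        model = make_point_model([(0, 0, 0)], element="X")
        with pytest.warns(UserWarning, match="unknown-element"):
            with pytest.raises(ValueError):
                debye_profile(model, q_grid)


class TestCoordinateRg:
    def test_two_equal_points_ten_angstrom_apart(self):
        model = make_point_model([(0, 0, 0), (10.0, 0, 0)])
        assert coordinate_rg(model, "uniform") == pytest.approx(5.0)

    def test_sphere_surface_rg_equals_radius(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(200, 3))
        half = 12.0 * v / np.linalg.norm(v, axis=1, keepdims=True)
        pts = np.vstack([half, -half])  # antipodal pairs center the cloud exactly
        model = make_point_model(pts)
        assert coordinate_rg(model, "uniform") == pytest.approx(12.0, rel=1e-9)

    def test_shell_delta_is_additive(self, bundle_compact):
        bare = coordinate_rg(bundle_compact)
        assert coordinate_rg(bundle_compact, shell_delta=1.5) == pytest.approx(bare + 1.5)

    def test_needs_two_atoms(self):
        with pytest.raises(ValueError):
            coordinate_rg(make_point_model([(0, 0, 0)]))


class TestGuinierFit:
    def test_exact_guinier_law_recovered_exactly(self):
        q = np.linspace(1e-3, 0.05, 80)
        rg_true = 28.6  # free-protein scale
        prof = ScatteringProfile(q, 250.0 * np.exp(-(q * rg_true) ** 2 / 3))
        fit = guinier_fit(prof)
        assert fit.rg == pytest.approx(rg_true, abs=1e-9)
        assert fit.i0 == pytest.approx(250.0, rel=1e-9)
        assert fit.q_range_used[1] * fit.rg <= 1.3 + 1e-9

    def test_gaussian_coil_oracle(self):
        # Debye coil: I(q) = 2 (exp(-x) + x - 1)/x^2, x = (q Rg)^2.
        # A coil leaves the Guinier regime earlier than a globule, so the
        # window is restricted to q*Rg <= 0.5 for an unbiased recovery.
        rg_true = 27.0
        q = np.linspace(1e-3, 0.12, 200)
        x = (q * rg_true) ** 2
        prof = ScatteringProfile(q, 2 * (np.exp(-x) + x - 1) / x ** 2)
        assert guinier_fit(prof, qrg_max=0.5).rg == pytest.approx(rg_true, abs=0.3)

    def test_uniform_sphere_closed_form(self):
        R = 10.0
        q = np.linspace(1e-4, 0.15, 300)
        x = q * R
        amplitude = 3 * (np.sin(x) - x * np.cos(x)) / x ** 3
        fit = guinier_fit(ScatteringProfile(q, amplitude ** 2))
        assert fit.rg == pytest.approx(np.sqrt(3.0 / 5.0) * R, rel=0.02)

    def test_agrees_with_coordinate_rg_for_compact_bundle(self, bundle_compact):
        q = np.linspace(0.0, 0.08, 120)
        prof = debye_profile(bundle_compact, q)
        rg_coord = coordinate_rg(bundle_compact, "electron")
        assert guinier_fit(prof).rg == pytest.approx(rg_coord, rel=0.02)

    def test_window_too_small_raises(self):
        prof = ScatteringProfile(np.linspace(0.01, 0.02, 4), np.ones(4))
        with pytest.raises(ValueError):
            guinier_fit(prof)

    def test_nonpositive_intensity_in_window_raises(self):
        q = np.linspace(1e-3, 0.05, 30)
        I = np.exp(-(q * 20) ** 2 / 3)
        I[2] = -1.0
        with pytest.raises(ValueError):
            guinier_fit(ScatteringProfile(q, I))


class TestChi2Compare:
    def test_pure_scaling_gives_zero_chi2_and_the_scale(self, profile_compact):
        exp = ScatteringProfile(
            profile_compact.q, 2.5 * profile_compact.intensity,
            sigma=0.03 * profile_compact.intensity + 1.0,
        )
        chi2, scale = chi2_compare(exp, profile_compact)
        assert chi2 == pytest.approx(0.0, abs=1e-18)
        assert scale == pytest.approx(2.5, rel=1e-12)

    def test_noise_at_sigma_gives_unit_chi2(self):
        rng = np.random.default_rng(11)
        q = np.linspace(0.0, 0.3, 1000)
        calc = ScatteringProfile(q, 1e4 * np.exp(-(q * 20) ** 2 / 3) + 10)
        sigma = 0.02 * calc.intensity
        exp = ScatteringProfile(q, calc.intensity + rng.normal(0, sigma), sigma=sigma)
        chi2, _ = chi2_compare(exp, calc)
        assert chi2 == pytest.approx(1.0, abs=3 * np.sqrt(2 / 1000))

    def test_missing_sigma_raises_with_guidance(self, profile_compact):
        with pytest.raises(ValueError, match="sigma"):
            chi2_compare(profile_compact, profile_compact)

    def test_mismatched_conformer_scores_far_worse(
        self, profile_compact, profile_extended
    ):
        noisy = simulate_mixture_profile(
            profile_compact, profile_extended, MixtureSpec(0.0, 0.01, seed=5)
        )
        chi2_match, _ = chi2_compare(noisy, profile_compact)
        chi2_mismatch, _ = chi2_compare(noisy, profile_extended)
        assert chi2_mismatch > 10 * chi2_match
        assert chi2_mismatch > 1.0


class TestTwoStateFit:
    def test_noise_free_composition_recovered_exactly(
        self, profile_compact, profile_extended
    ):
        mixed = simulate_mixture_profile(
            profile_compact, profile_extended, MixtureSpec(0.125, 0.0)
        )
        fit = two_state_fit(mixed, profile_compact, profile_extended)
        assert fit.fraction_open == pytest.approx(0.125, abs=1e-12)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_pure_closed_input_gives_zero_fraction(
        self, profile_compact, profile_extended
    ):
        exp = ScatteringProfile(
            profile_compact.q, profile_compact.intensity,
            sigma=0.01 * profile_compact.intensity + 1e-9,
        )
        fit = two_state_fit(exp, profile_compact, profile_extended)
        assert fit.fraction_open == 0.0

    def test_component_radii_are_ordered(self, profile_compact, profile_extended):
        mixed = simulate_mixture_profile(
            profile_compact, profile_extended, MixtureSpec(0.2, 0.0)
        )
        fit = two_state_fit(mixed, profile_compact, profile_extended)
        assert fit.profile_open_rg > fit.profile_closed_rg

    def test_recovery_bias_below_grid_step(self, profile_compact, profile_extended):
        recovered = []
        for seed in range(40):
            mixed = simulate_mixture_profile(
                profile_compact, profile_extended, MixtureSpec(0.2, 0.02, seed=seed)
            )
            recovered.append(
                two_state_fit(mixed, profile_compact, profile_extended).fraction_open
            )
        assert abs(np.mean(recovered) - 0.2) < 0.005


class TestNStateFit:
    def test_single_component_reduces_to_chi2_compare(self, profile_compact):
        exp = ScatteringProfile(
            profile_compact.q, 3.0 * profile_compact.intensity,
            sigma=0.02 * profile_compact.intensity + 1e-9,
        )
        weights, scale, chi2 = nstate_fit(exp, [profile_compact])
        np.testing.assert_allclose(weights, [1.0])
        assert scale == pytest.approx(3.0, rel=1e-9)
        assert chi2 == pytest.approx(chi2_compare(exp, profile_compact)[0], abs=1e-12)

    def test_three_component_recovery_noise_free(self, q_grid):
        comps = [
            debye_profile(build_helix_bundle(4, 20, s), q_grid)
            for s in (8.0, 11.0, 15.0)
        ]
        true_w = np.array([0.7, 0.2, 0.1])
        mixed_i = sum(w * c.intensity for w, c in zip(true_w, comps))
        exp = ScatteringProfile(q_grid, mixed_i, sigma=1e-4 * mixed_i + 1e-12)
        weights, scale, _ = nstate_fit(exp, comps)
        np.testing.assert_allclose(weights, true_w, atol=1e-6)
        assert scale == pytest.approx(1.0, abs=1e-6)

    def test_two_components_agree_with_grid_scan(
        self, profile_compact, profile_extended
    ):
        mixed = simulate_mixture_profile(
            profile_compact, profile_extended, MixtureSpec(0.33, 0.01, seed=2)
        )
        weights, _, _ = nstate_fit(mixed, [profile_compact, profile_extended])
        grid = two_state_fit(mixed, profile_compact, profile_extended, grid_step=0.005)
        assert weights[1] == pytest.approx(grid.fraction_open, abs=0.005)


class TestRgMix:
    def test_equal_radii_regardless_of_composition(self):
        assert rg_mix(RgMixInputs(3.0, 97.0, 26.9, 26.9)) == pytest.approx(26.9)

    def test_major_minor_composition_value(self):
        # direct evaluation of the mixture rule at the two-conformer radii
        value = rg_mix(RgMixInputs(87.5, 12.5, 26.9, 32.2))
        assert value == pytest.approx(27.618, abs=0.001)

    def test_vanishing_minor_component(self):
        assert rg_mix(RgMixInputs(50.0, 0.0, 26.9, 32.2)) == pytest.approx(26.9)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            RgMixInputs(0.0, 0.0, 20.0, 30.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        c_a=st.floats(0.0, 100.0),
        c_b=st.floats(0.0, 100.0),
        rg_a=st.floats(5.0, 50.0),
        rg_b=st.floats(5.0, 50.0),
    )
    def test_apparent_rg_brackets_component_radii(self, c_a, c_b, rg_a, rg_b):
        if c_a + c_b == 0:
            return
        value = rg_mix(RgMixInputs(c_a, c_b, rg_a, rg_b))
        assert min(rg_a, rg_b) - 1e-9 <= value <= max(rg_a, rg_b) + 1e-9

    def test_monotone_in_minor_fraction_when_minor_is_larger(self):
        # only a larger minor conformer can raise the apparent Rg
        values = [
            rg_mix(RgMixInputs(100.0 - cb, cb, 26.9, 32.2)) for cb in (0, 5, 12.5, 30, 60)
        ]
        assert all(a < b for a, b in zip(values, values[1:]))


class TestProfileIO:
    def test_three_column_round_trip(self, tmp_path, profile_compact):
        p = tmp_path / "prof.dat"
        prof = ScatteringProfile(
            profile_compact.q, profile_compact.intensity,
            sigma=0.01 * profile_compact.intensity + 1.0,
        )
        write_profile(prof, p, header="round trip")
        back = read_profile(p)
        np.testing.assert_allclose(back.q, prof.q, rtol=1e-8)
        np.testing.assert_allclose(back.intensity, prof.intensity, rtol=1e-8)
        np.testing.assert_allclose(back.sigma, prof.sigma, rtol=1e-8)

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            ScatteringProfile(np.array([0.2, 0.1]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            ScatteringProfile(np.array([0.1, 0.2]), np.array([1.0]))
        with pytest.raises(ValueError):
            ScatteringProfile(np.array([0.1, 0.2]), np.array([1.0, 1.0]),
                              sigma=np.array([0.1, -0.1]))
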