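"""Unit and property tests for the SLS/DLS evaluation chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.testing import assert_allclose

from picquant.errors import FitError, ParameterError
from picquant.scattering import (
    DEFAULT_ANGLES_DEG,
    KB,
    N_AVOGADRO,
    ScatteringCalibration,
    ScatteringFrame,
    analyze_series,
    contrast_factor,
    contrast_factor_from,
    cumulant_fit,
    detect_induction_time,
    diffusion_from_radius,
    excess_rayleigh,
    extrapolate_Dz,
    guinier_fit,
    momentum_transfer,
    rho_ratio,
    stokes_einstein,
    zimm_fit,
)


def normal_equations_line(x, y):
    """Brute-force normal-equations oracle for a straight-line fit."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    design = np.column_stack([np.ones_like(x), x])
    coef = np.linalg.solve(design.T @ design, design.T @ y)
    return coef[0], coef[1]


class TestMomentumTransfer:
    def test_zero_angle(self):
        assert momentum_transfer(0.0, 1.332, 632.8) == 0.0

    def test_printed_q_range_bounds(self):
        # 30 and 86 degrees bracket the detector bank; printed bounds are
        # 6.8e-3 and 18e-3 1/nm at two significant figures
        q30 = momentum_transfer(30.0, 1.332, 632.8)
        q86 = momentum_transfer(86.0, 1.332, 632.8)
        assert float(f"{q30:.1e}") == 6.8e-3
        assert float(f"{q86:.1e}") == 1.8e-2

    def test_q_at_90_degrees(self):
        # direct arithmetic: (4 pi 1.332 / 632.8) * sin(45 deg)
        expected = 4 * np.pi * 1.332 / 632.8 * np.sin(np.radians(45.0))
        assert_allclose(momentum_transfer(90.0, 1.332, 632.8), expected, rtol=1e-12)
        assert_allclose(expected, 1.870e-2, rtol=1e-3)

    def test_rejects_out_of_range(self):
        with pytest.raises(ParameterError):
            momentum_transfer(-1.0, 1.332, 632.8)
        with pytest.raises(ParameterError):
            momentum_transfer(180.0, 1.332, 632.8)

    @given(
        st.floats(min_value=1.0, max_value=178.0),
        st.floats(min_value=0.5, max_value=178.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_theta(self, a, b):
        qa = momentum_transfer(a, 1.332, 632.8)
        qb = momentum_transfer(b, 1.332, 632.8)
        assert (a < b) == (qa < qb) or a == b


class TestExcessRayleigh:
    def test_no_excess(self):
        d_r, usable = excess_rayleigh([1.0, 2.0], [1.0, 2.0], [5.0, 5.0], 1e-5)
        assert_allclose(d_r, 0.0)
        assert not usable.any()

    def test_forced_by_formula(self):
        d_r, _ = excess_rayleigh([2.0], [1.0], [10.0], 1e-5)
        assert_allclose(d_r, [1e-6], rtol=1e-12)

    def test_linearity_in_standard_ratio(self):
        d1, _ = excess_rayleigh([3.0], [1.0], [4.0], 1e-5)
        d2, _ = excess_rayleigh([3.0], [1.0], [4.0], 2e-5)
        assert_allclose(d2, 2 * d1)

    def test_negative_excess_flagged(self):
        d_r, usable = excess_rayleigh([1.0, 3.0], [2.0, 1.0], [4.0, 4.0], 1e-5)
        assert list(usable) == [False, True]


class TestContrastFactor:
    def test_zero_dndc(self):
        assert contrast_factor_from(1.496, 632.8, 0.0) == 0.0

    def test_quadratic_in_dndc(self):
        k1 = contrast_factor_from(1.496, 632.8, 0.187)
        k2 = contrast_factor_from(1.496, 632.8, 2 * 0.187)
        assert_allclose(k2, 4 * k1, rtol=1e-12)

    def test_against_dimensional_hand_calculation(self, calib):
        # independent unit-tracked recomputation: lambda in cm, dn/dc cm^3/g
        lam_cm = 632.8e-7
        expected = (2 * np.pi * 1.496 * 0.187) ** 2 / (N_AVOGADRO * lam_cm**4)
        assert_allclose(contrast_factor(calib), expected, rtol=1e-12)
        # magnitude sanity: ~3.2e-7 cm^2 mol / g^2
        assert 3.0e-7 < expected < 3.4e-7


class TestZimmFit:
    def test_exact_recovery(self, calib, q_grid):
        mw, rg = 1e5, 20.0
        k = contrast_factor(calib)
        c = calib.conc_g_l * 1e-3
        y = 1 / mw + rg**2 * q_grid**2 / (3 * mw)  # A2 = 0
        d_r = k * c / y
        res = zimm_fit(q_grid, d_r, calib)
        assert_allclose(res.Mw_g_mol, mw, rtol=1e-9)
        assert_allclose(res.Rg_nm, rg, rtol=1e-9)

    def test_point_scatterer_rg_zero(self, calib, q_grid):
        d_r = np.full_like(q_grid, 1e-4)
        res = zimm_fit(q_grid, d_r, calib)
        assert res.Rg_nm == pytest.approx(0.0, abs=1e-3)  # numerically zero at nm scale

    def test_two_concentration_a2_recovery(self, calib, q_grid):
        mw, rg, a2 = 2e5, 15.0, 1e-4
        k = contrast_factor(calib)
        concs_g_l = np.concatenate([np.full(8, 0.5), np.full(8, 2.0)])
        q = np.concatenate([q_grid, q_grid])
        c_gcm3 = concs_g_l * 1e-3
        y = 1 / mw + rg**2 * q**2 / (3 * mw) + 2 * a2 * c_gcm3
        d_r = k * c_gcm3 / y
        res = zimm_fit(q, d_r, calib, conc_g_l=concs_g_l)
        assert_allclose(res.A2_ml_mol_g2, a2, rtol=0.01)
        assert_allclose(res.Mw_g_mol, mw, rtol=0.01)

    def test_too_few_angles(self, calib, q_grid):
        with pytest.raises(FitError):
            zimm_fit(q_grid[:2], np.array([1e-4, 1e-4]), calib)


class TestGuinierFit:
    def test_exact_recovery(self, calib, q_grid):
        mw, rg = 1e6, 50.0
        k = contrast_factor(calib)
        c = calib.conc_g_l * 1e-3
        d_r = k * c * mw * np.exp(-(q_grid**2) * rg**2 / 3)
        res = guinier_fit(q_grid, d_r, calib)
        assert_allclose(res.Mw_g_mol, mw, rtol=1e-6)
        assert_allclose(res.Rg_nm, rg, rtol=1e-6)

    def test_rg_zero_input(self, calib, q_grid):
        mw = 1e5
        d_r = np.full_like(q_grid, contrast_factor(calib) * calib.conc_g_l * 1e-3 * mw)
        res = guinier_fit(q_grid, d_r, calib)
        assert res.Rg_nm == 0.0
        assert_allclose(res.Mw_g_mol, mw, rtol=1e-9)

    def test_sphere_form_factor_rg(self, calib, q_grid):
        # brute-force sphere form-factor simulation, R = 30 nm
        radius = 30.0
        u = q_grid * radius
        form = (3 * (np.sin(u) - u * np.cos(u)) / u**3) ** 2
        d_r = contrast_factor(calib) * calib.conc_g_l * 1e-3 * 1e8 * form
        res = guinier_fit(q_grid, d_r, calib)
        assert_allclose(res.Rg_nm, np.sqrt(3.0 / 5.0) * radius, rtol=0.03)

    def test_nonpositive_dropped_then_error(self, calib, q_grid):
        d_r = np.array([-1.0, -1.0, -1.0, -1.0, -1.0, -1.0, 1e-4, 1e-4])
        with pytest.raises(FitError):
            guinier_fit(q_grid, d_r, calib)

    def test_warns_outside_validity(self, calib, q_grid):
        mw, rg = 1e9, 200.0
        d_r = (
            contrast_factor(calib) * calib.conc_g_l * 1e-3 * mw
            * np.exp(-(q_grid**2) * rg**2 / 3)
        )
        with pytest.warns(UserWarning, match="validity"):
            guinier_fit(q_grid, d_r, calib)


class TestCumulantFit:
    def test_single_exponential_exact(self):
        q_nm = 0.01
        d_true = 1e-12
        tau = np.logspace(-6, 1, 80)
        g1 = np.exp(-((q_nm * 1e9) ** 2) * d_true * tau)
        d_fit, k2, _ = cumulant_fit(tau, g1, q_nm)
        assert_allclose(d_fit, d_true, rtol=1e-9)
        assert abs(k2) < 1e-9

    def test_bimodal_positive_k2(self):
        # oracle: second cumulant of a decay-rate mixture is its variance
        q_nm = 0.01
        q_m = q_nm * 1e9
        d1, d2, w = 1e-12, 4e-12, 0.5
        tau = np.logspace(-6, 0, 200)
        g1 = w * np.exp(-(q_m**2) * d1 * tau) + (1 - w) * np.exp(-(q_m**2) * d2 * tau)
        d_fit, k2, _ = cumulant_fit(tau, g1, q_nm)
        assert k2 > 0
        assert d1 < d_fit < d2

    def test_intercept_offset(self):
        q_nm = 0.01
        tau = np.logspace(-6, 1, 80)
        g1 = 0.95 * np.exp(-((q_nm * 1e9) ** 2) * 1e-12 * tau)
        _, _, intercept = cumulant_fit(tau, g1, q_nm)
        assert_allclose(intercept, np.log(0.95), atol=1e-9)

    def test_non_decaying_errors(self):
        tau = np.logspace(-6, 0, 50)
        with pytest.raises(FitError):
            cumulant_fit(tau, np.ones_like(tau), 0.01)


class TestExtrapolateDz:
    def test_q_independent(self, q_grid):
        d = np.full(q_grid.size, 2e-12)
        dz, slope, _, flags = extrapolate_Dz(d, q_grid)
        assert_allclose(dz, 2e-12, rtol=1e-12)
        assert abs(slope) < 1e-20
        assert flags == []

    def test_planted_linear(self, q_grid):
        dz_true, slope_true = 1e-12, 3e-9
        d = dz_true + slope_true * q_grid**2
        dz, slope, _, _ = extrapolate_Dz(d, q_grid)
        assert_allclose(dz, dz_true, rtol=1e-10)
        assert_allclose(slope, slope_true, rtol=1e-10)

    def test_noisy_mean_recovery(self, q_grid):
        dz_true = 1e-12
        d_clean = dz_true * (1 + 0.1 * (q_grid / q_grid.max()) ** 2)
        estimates = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            d = d_clean * (1 + rng.normal(0, 0.01, d_clean.shape))
            estimates.append(extrapolate_Dz(d, q_grid)[0])
        assert_allclose(np.mean(estimates), dz_true, rtol=0.005)

    def test_fallback_mean(self, q_grid):
        d = np.full(q_grid.size, np.nan)
        d[0] = d[1] = 1e-12
        dz, _, _, flags = extrapolate_Dz(d, q_grid)
        assert "fallback_mean_D" in flags
        assert_allclose(dz, 1e-12)


class TestStokesEinstein:
    def test_direct_arithmetic(self, calib):
        # kB*298.15 / (6 pi * 8.91e-4 * 2.45e-12) ~ 100 nm
        rh = stokes_einstein(2.45e-12, calib)
        expected = KB * 298.15 / (6 * np.pi * 8.91e-4 * 2.45e-12) * 1e9
        assert_allclose(rh, expected, rtol=1e-12)
        assert_allclose(rh, 100.0, rtol=0.01)

    def test_inverse_proportionality(self, calib):
        assert_allclose(
            stokes_einstein(2e-12, calib), stokes_einstein(1e-12, calib) / 2
        )

    def test_round_trip(self, calib):
        rh0 = 37.5
        assert_allclose(
            stokes_einstein(float(diffusion_from_radius(rh0, calib)), calib),
            rh0,
            rtol=1e-12,
        )

    def test_rejects_nonpositive(self, calib):
        with pytest.raises(ParameterError):
            stokes_einstein(0.0, calib)


class TestRhoRatio:
    def test_equal_radii(self):
        assert rho_ratio(10.0, 10.0) == 1.0

    def test_solid_sphere(self):
        radius = 42.0
        rho = rho_ratio(np.sqrt(3.0 / 5.0) * radius, radius)
        assert_allclose(rho, 0.7745966692414834, rtol=1e-12)  # sqrt(3/5)
        assert round(rho, 1) == 0.8  # printed value 0.78 at its precision

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, scale):
        assert_allclose(rho_ratio(3.0 * scale, 4.0 * scale), 0.75, rtol=1e-9)


class TestInductionDetection:
    def test_constant_baseline_never(self):
        t = np.arange(10.0)
        mw = np.full(10, 1e5)
        assert detect_induction_time(t, mw, mw[:4]) is None

    def test_planted_step(self):
        t = np.arange(20.0)
        mw = np.full(20, 1e5)
        mw[12:] = 5e5
        assert detect_induction_time(t, mw, mw[:5]) == 12.0


class TestAnalyzeSeries:
    def test_requires_frames_and_order(self, calib):
        with pytest.raises(ParameterError):
            analyze_series([], calib)

    def test_no_baseline_flagged(self, calib, growth_model):
        from picquant.synth import generate_scattering_series

        frames = generate_scattering_series(
            growth_model, calib, n_frames=8, pre_frames=0, seed=0
        )
        _, induction, flags = analyze_series(frames, calib)
        assert induction is None
        assert "no_baseline_frames" in flags


class TestLinearFitOracle:
    """All linear fits agree with brute-force normal equations to 1e-10."""

    def test_guinier_matches_normal_equations(self, calib, q_grid):
        rng = np.random.default_rng(0)
        d_r = 1e-4 * np.exp(-(q_grid**2) * 900) * (1 + rng.normal(0, 0.02, 8))
        res = guinier_fit(q_grid, d_r, calib)
        y = np.log(contrast_factor(calib) * calib.conc_g_l * 1e-3 / d_r)
        intercept, slope = normal_equations_line(q_grid**2, y)
        assert_allclose(res.Mw_g_mol, np.exp(-intercept), rtol=1e-10)
        assert_allclose(res.Rg_nm, np.sqrt(3 * slope), rtol=1e-10)

    def test_zimm_matches_normal_equations(self, calib, q_grid):
        rng = np.random.default_rng(1)
        d_r = 1e-4 / (1 + (q_grid * 30) ** 2 / 3) * (1 + rng.normal(0, 0.02, 8))
        res = zimm_fit(q_grid, d_r, calib)
        y = contrast_factor(calib) * calib.conc_g_l * 1e-3 / d_r
        intercept, slope = normal_equations_line(q_grid**2, y)
        assert_allclose(res.Mw_g_mol, 1 / intercept, rtol=1e-10)
        assert_allclose(res.Rg_nm, np.sqrt(3 * slope / intercept), rtol=1e-10)

    def test_dz_matches_normal_equations(self, q_grid):
        rng = np.random.default_rng(2)
        d = 1e-12 * (1 + rng.normal(0, 0.05, q_grid.size))
        dz, slope, _, _ = extrapolate_Dz(d, q_grid)
        intercept_o, slope_o = normal_equations_line(q_grid**2, d)
        assert_allclose(dz, intercept_o, rtol=1e-10)
        assert_allclose(slope, slope_o, rtol=1e-10, atol=1e-30)


class TestGuinierZimmAgreement:
    def test_small_particle_limit(self, calib, q_grid):
        # qRg < 0.5: both linearizations agree on Mw to < 1%
        mw, rg = 1e5, 20.0  # qmax*Rg = 0.36
        k = contrast_factor(calib)
        c = calib.conc_g_l * 1e-3
        d_r = k * c * mw * np.exp(-(q_grid**2) * rg**2 / 3)
        mw_g = guinier_fit(q_grid, d_r, calib).Mw_g_mol
        mw_z = zimm_fit(q_grid, d_r, calib).Mw_g_mol
        assert abs(mw_g - mw_z) / mw_g < 0.01


class TestFrameValidation:
    def test_bad_angles(self):
        with pytest.raises(ParameterError):
            ScatteringFrame(
                t_s=0.0,
                angles_deg=[30, 30, 40],
                r_sol=[1, 1, 1],
                r_solv=[0, 0, 0],
                r_std=[1, 1, 1],
            )

    def test_g1_exceeding_unity(self):
        with pytest.raises(ParameterError):
            ScatteringFrame(
                t_s=0.0,
                angles_deg=DEFAULT_ANGLES_DEG,
                r_sol=np.ones(8),
                r_solv=np.zeros(8),
                r_std=np.ones(8),
                tau_s=[1e-5, 1e-4],
                g1=np.full((8, 2), 1.2),
            )
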