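"""Point-wise reaction dynamics, nullcline algebra, excitability."""

import dataclasses

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from stencen import model_core as mc
from stencen.params import CENParams, ConfigError, ModelParams, STENParams


class TestRates:
    def test_sten_rest_origin(self, sten):
        df, dr = mc.sten_rates(0.0, 0.0, 0.0, sten)
        assert df == pytest.approx(sten.a5s)
        assert dr == pytest.approx(0.0)

    def test_sten_hill_half_saturation(self, sten):
        f = sten.a4s
        df, dr = mc.sten_rates(f, 0.0, 0.0, sten)
        assert df == pytest.approx(-sten.a1s * f + sten.a3s / 2 + sten.a5s)
        assert dr == pytest.approx(sten.eps_s * sten.c1s * f)

    def test_resting_equilibrium_is_fixed_point(self, sten):
        f_star, r_star = mc.resting_equilibrium(sten)
        df, dr = mc.sten_rates(f_star, r_star, 0.0, sten)
        assert abs(df) < 1e-10
        assert abs(dr) < 1e-10

    def test_cen_rest_origin(self, cen):
        df, dr = mc.cen_rates(0.0, 0.0, 0.0, cen)
        assert df == pytest.approx(cen.a5c)
        assert dr == pytest.approx(0.0)

    def test_cen_coupling_offsets_inhibition(self, cen):
        # only the difference R_C - s_in enters the activator rate
        df_ref, _ = mc.cen_rates(0.7, 0.0, 0.0, cen)
        df_off, _ = mc.cen_rates(0.7, 1.3, 1.3, cen)
        assert df_off == pytest.approx(df_ref)

    def test_cen_fires_at_peak_coupling(self, cen, sten):
        # at peak STEN output the CEN activator nullcline minimum drops below
        # the resting inhibitor level: the rest state is destabilized
        _, r_rest = mc.resting_equilibrium(cen)
        s_in = mc.coupling_input(1.0, cen, sten.r0)  # rising STEN output
        roots = mc.nullcline_roots(r_rest, cen, s_in=float(s_in))
        # only the excited root survives: rest root is gone
        assert len(roots) == 1
        assert roots[0] > 1.0
        # at full wave peak the effective inhibition drops below the
        # nullcline entirely: no rest state at all
        s_in_max = mc.coupling_input(2.2, cen, sten.r0)
        assert mc.nullcline_roots(r_rest, cen, s_in=float(s_in_max)) == []

    def test_non_finite_rejected(self, sten, cen, params):
        with pytest.raises(ValueError):
            mc.sten_rates(np.nan, 0.0, 0.0, sten)
        with pytest.raises(ValueError):
            mc.cen_rates(0.0, np.inf, 0.0, cen)
        with pytest.raises(ValueError):
            mc.feedback_rates(np.nan, 0.0, 0.0, params.feedback)

    def test_feedback_steady_state(self, params):
        fb = params.feedback
        dz, dw = mc.feedback_rates(fb.p2 / fb.p1 * 0.8, 0.0, 0.8, fb)
        assert dz == pytest.approx(0.0)
        dz, dw = mc.feedback_rates(0.4, 0.3, 0.0, fb)
        assert dz < 0 and dw < 0  # pure decay without input

    def test_feedback_gain_ratio_is_two(self, params):
        fb = params.feedback
        z_star = fb.p2 / fb.p1 * 1.0
        w_star = fb.p4 / fb.p3 * 1.0
        assert w_star / z_star == pytest.approx(2.0)

    def test_cen_eightfold_faster(self, params):
        assert params.cen.eps_c / params.sten.eps_s == pytest.approx(8.0)


class TestCouplingAndNoise:
    def test_coupling_zero_at_reference(self, cen, sten):
        assert mc.coupling_input(sten.r0, cen, sten.r0) == pytest.approx(0.0)

    def test_coupling_linear(self, cen):
        p = dataclasses.replace(cen, s_c=0.5)
        assert mc.coupling_input(1.0, p, 0.0) == pytest.approx(0.5)
        p0 = dataclasses.replace(cen, s_c=0.0)
        assert mc.coupling_input(7.3, p0, 0.1) == 0.0

    def test_noise_sigma_values(self, sten):
        assert mc.noise_sigma(0.4, 0.4, sten) == pytest.approx(sten.u_b)
        p = dataclasses.replace(sten, u_b=0.2)
        assert mc.noise_sigma(0.5, 0.3, p) == pytest.approx(0.4)
        p = dataclasses.replace(sten, u_b=0.1)
        assert mc.noise_sigma(0.0, 0.5, p) == 0.0  # clamped

    @given(z=st.floats(0, 10), w=st.floats(0, 10), ub=st.floats(0, 2))
    @settings(deadline=None, max_examples=50)
    def test_noise_sigma_nonnegative(self, z, w, ub):
        p = STENParams(u_b=ub)
        s = mc.noise_sigma(z, w, p)
        assert s >= 0.0
        if ub + z - w > 0:
            assert s == pytest.approx(ub + z - w)


class TestNullclines:
    def test_high_inhibition_single_root(self, sten):
        roots = mc.nullcline_roots(5.0, sten)
        assert len(roots) == 1

    def test_bistable_window_three_roots(self, sten):
        (f_min, r_min), (f_max, r_max) = mc.nullcline_fold(sten)
        r_mid = 0.5 * (r_min + r_max)
        roots = mc.nullcline_roots(r_mid, sten)
        assert len(roots) == 3
        assert roots[0] < roots[1] < roots[2]

    def test_roots_are_roots(self, sten):
        for r in (0.7, 1.2, 2.5):
            for rho in mc.nullcline_roots(r, sten):
                assert abs(mc.activator_rate(rho, r, sten)) < 1e-8

    @pytest.mark.parametrize("r", [0.55, 0.9, 1.5, 2.0, 3.0])
    def test_roots_match_brute_force_scan(self, sten, r):
        # independent oracle: dense sign-change scan at 1e-4 resolution
        fmax = (sten.a3s + sten.a5s) / sten.a1s + 2
        fs = np.arange(0.0, fmax, 1e-4)
        gs = mc.activator_rate(fs, r, sten)
        sign_flips = np.where(np.sign(gs[:-1]) * np.sign(gs[1:]) < 0)[0]
        brute = 0.5 * (fs[sign_flips] + fs[sign_flips + 1])
        roots = mc.nullcline_roots(r, sten)
        assert len(roots) == len(brute)
        np.testing.assert_allclose(roots, brute, atol=1e-4)

    def test_symbolic_rederivation(self, sten, cen, params, rng):
        # independent symbolic construction of the displayed rate laws
        F, R, U = sympy.symbols("F R U")
        a1, a2, a3, a4, a5, eps, c1 = sympy.symbols("a1 a2 a3 a4 a5 eps c1")
        act = -(a1 + a2 * R) * F + a3 * F**2 / (a4**2 + F**2) + a5 + U
        inh = eps * (-R + c1 * F)
        f_act = sympy.lambdify((F, R, U, a1, a2, a3, a4, a5), act, "numpy")
        f_inh = sympy.lambdify((F, R, eps, c1), inh, "numpy")
        fs = rng.uniform(0, 8, 1000)
        rs = rng.uniform(0, 4, 1000)
        us = rng.uniform(-0.5, 0.5, 1000)
        df, dr = mc.sten_rates(fs, rs, us, sten)
        ref_df = f_act(fs, rs, us, sten.a1s, sten.a2s, sten.a3s, sten.a4s, sten.a5s)
        ref_dr = f_inh(fs, rs, sten.eps_s, sten.c1s)
        np.testing.assert_allclose(df, ref_df, rtol=1e-10)
        np.testing.assert_allclose(dr, ref_dr, rtol=1e-10)
        # CEN: coupling enters as R - s_in
        sin = rng.uniform(-0.5, 1.5, 1000)
        dfc, drc = mc.cen_rates(fs, rs, sin, cen)
        ref_dfc = f_act(fs, rs - sin, 0.0, cen.a1c, cen.a2c, cen.a3c, cen.a4c,
                        cen.a5c)
        np.testing.assert_allclose(dfc, ref_dfc, rtol=1e-10)


class TestExcitability:
    def test_default_is_excitable(self, sten, cen):
        assert mc.is_excitable(sten)
        assert mc.is_excitable(cen)

    def test_no_positive_feedback_is_not_excitable(self, sten):
        p = dataclasses.replace(sten, a3s=0.0)
        assert not mc.is_excitable(p)

    def test_supra_threshold_excursion(self, sten):
        # reaction-only ODE oracle: a supra-threshold kick produces a large
        # excursion (peak > 5x the perturbation) before returning to rest
        f_star, r_star = mc.resting_equilibrium(sten)

        def rhs(t, y):
            df, dr = mc.sten_rates(y[0], y[1], 0.0, sten)
            return [float(df), float(dr)]

        kick = 0.15
        sol = solve_ivp(rhs, [0, 200], [f_star + kick, r_star],
                        rtol=1e-8, atol=1e-10, max_step=1.0)
        peak = sol.y[0].max() - f_star
        assert peak > 5 * kick
        assert abs(sol.y[0][-1] - f_star) < 1e-3
        assert abs(sol.y[1][-1] - r_star) < 1e-3

    def test_sub_threshold_decays(self, sten):
        f_star, r_star = mc.resting_equilibrium(sten)

        def rhs(t, y):
            df, dr = mc.sten_rates(y[0], y[1], 0.0, sten)
            return [float(df), float(dr)]

        kick = 0.03
        sol = solve_ivp(rhs, [0, 100], [f_star + kick, r_star],
                        rtol=1e-8, atol=1e-10, max_step=1.0)
        assert sol.y[0].max() - f_star < 2 * kick


class TestConfig:
    def test_round_trip(self):
        p = ModelParams()
        p.sten.a3s = 11.25
        p.cen.sigma_c = 0.4
        q = ModelParams.from_config_text(p.to_config_text())
        assert q.sten.a3s == 11.25
        assert q.cen.sigma_c == 0.4
        assert q.to_config_text() == p.to_config_text()

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError, match="unknown parameter"):
            ModelParams.from_config_text("a3s = 10\nbogus = 1\n")

    def test_duplicate_key_rejected(self):
        with pytest.raises(ConfigError, match="duplicate"):
            ModelParams.from_config_text("a3s = 10\na3s = 11\n")

    def test_negative_value_rejected(self):
        with pytest.raises(ConfigError):
            ModelParams.from_config_text("a3s = -1\n")

    def test_parameter_paths(self):
        p = ModelParams()
        p.set("a3c", 12.5)
        assert p.cen.a3c == 12.5
        assert p.get("eps_s") == p.sten.eps_s
        with pytest.raises(KeyError):
            p.get("nonexistent")
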