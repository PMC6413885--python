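"""Stochastic reaction-diffusion integration: stencils, stepping, presets."""

import dataclasses

import numpy as np
import pytest

from stencen import model_core as mc
from stencen import simulate as sim
from stencen.params import ModelParams


class TestLaplacian:
    def test_constant_field_is_zero(self):
        for boundary in ("no-flux", "periodic"):
            g = sim.GridSpec((12, 9), boundary=boundary)
            f = np.full(g.shape, 3.7)
            assert np.abs(sim.laplacian(f, g)).max() < 1e-12

    def test_parabola_interior(self):
        g = sim.GridSpec((20,))
        f = np.arange(20.0) ** 2
        np.testing.assert_allclose(sim.laplacian(f, g)[1:-1], 2.0)

    def test_2d_parabola(self):
        g = sim.GridSpec((10, 10), spacing=0.5)
        y, x = np.mgrid[0:10, 0:10] * 0.5
        np.testing.assert_allclose(
            sim.laplacian(x**2 + y**2, g)[1:-1, 1:-1], 4.0, rtol=1e-12)

    def test_periodic_sine_eigenmode(self):
        n = 16
        g = sim.GridSpec((n,), boundary="periodic")
        k = 2 * np.pi * 3 / n
        f = np.sin(k * np.arange(n))
        lam = (2 * np.cos(k) - 2) / g.spacing**2
        np.testing.assert_allclose(sim.laplacian(f, g), lam * f, atol=1e-12)

    def test_no_flux_conserves_mass(self, rng):
        g = sim.GridSpec((30, 30))
        f = rng.uniform(0, 1, g.shape)
        assert sim.laplacian(f, g).sum() == pytest.approx(0.0, abs=1e-9)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            sim.laplacian(np.zeros(5), sim.GridSpec((6,)))


class TestStep:
    def test_equilibrium_is_stationary_without_noise(self):
        p = ModelParams()
        p.sten.u_b = 0.0
        p.cen.sigma_c = 0.0
        g = sim.GridSpec((16, 16))
        st = sim.initial_state(p, g, seed=0)
        st2 = st
        dt = sim.default_dt(p, g)
        for _ in range(50):
            st2 = sim.step(st2, p, dt, g)
        for name in sim.FIELD_NAMES:
            np.testing.assert_allclose(getattr(st2, name), getattr(st, name),
                                       atol=1e-9)

    def test_bit_exact_reproducibility(self):
        p = ModelParams()
        g = sim.GridSpec((12, 12))
        dt = sim.default_dt(p, g)

        def advance(seed):
            st = sim.initial_state(p, g, seed=seed)
            for _ in range(30):
                st = sim.step(st, p, dt, g)
            return st

        a, b = advance(42), advance(42)
        for name in sim.FIELD_NAMES:
            assert np.array_equal(getattr(a, name), getattr(b, name))
        c = advance(43)
        assert not np.array_equal(a.F_S, c.F_S)

    def test_stability_bound_enforced(self):
        p = ModelParams()
        g = sim.GridSpec((16,))
        st = sim.initial_state(p, g)
        with pytest.raises(ValueError, match="stability"):
            sim.step(st, p, 10 * sim.stability_limit(p, g), g)

    def test_mean_increment_matches_deterministic_rate(self):
        # Monte-Carlo oracle: a uniform 100x100 state gives 1e4 iid samples
        # of one Euler-Maruyama increment
        p = ModelParams()
        g = sim.GridSpec((100, 100))
        st = sim.initial_state(p, g, seed=7)
        st.F_S += 0.3  # displaced state so the drift is nonzero
        dt = 0.01
        f0 = st.F_S.copy()
        st2 = sim.step(st, p, dt, g)
        inc = (st2.F_S - f0).ravel()
        drift, _ = mc.sten_rates(f0[0, 0], st.R_S[0, 0], 0.0, p.sten)
        sigma = float(mc.noise_sigma(st.Z_C[0, 0], st.W_C[0, 0], p.sten))
        sem = sigma * np.sqrt(dt) / np.sqrt(inc.size)
        assert abs(inc.mean() - float(drift) * dt) < 3 * sem

    def test_fields_stay_nonnegative(self):
        p = ModelParams()
        p.sten.u_b = 3.0  # violent noise
        g = sim.GridSpec((20, 20))
        st = sim.initial_state(p, g, seed=1)
        dt = sim.default_dt(p, g)
        for _ in range(100):
            st = sim.step(st, p, dt, g)
        assert st.F_S.min() >= 0.0
        assert st.F_C.min() >= 0.0


class TestTrigger:
    def test_adds_only_to_activator(self):
        p = ModelParams()
        g = sim.GridSpec((30,))
        st = sim.initial_state(p, g)
        st2 = sim.trigger(st, slice(5, 10), 1.5)
        assert np.allclose(st2.F_S[5:10] - st.F_S[5:10], 1.5)
        assert np.array_equal(st2.R_S, st.R_S)
        assert np.array_equal(st2.F_C, st.F_C)

    def test_disc_trigger(self):
        p = ModelParams()
        g = sim.GridSpec((20, 20))
        st = sim.initial_state(p, g)
        st2 = sim.trigger(st, sim.Disc((10, 10), 3.0), 1.0)
        assert st2.F_S[10, 10] > st.F_S[10, 10]
        assert st2.F_S[0, 0] == st.F_S[0, 0]
        n_hit = int((st2.F_S > st.F_S).sum())
        assert 20 <= n_hit <= 40  # ~pi*9

    def test_out_of_grid_raises(self):
        p = ModelParams()
        st = sim.initial_state(p, sim.GridSpec((10,)))
        with pytest.raises(IndexError):
            sim.trigger(st, 15, 1.0)


class TestRamp:
    def test_linear_interpolation(self):
        p = ModelParams()
        sched = sim.PerturbationSchedule([sim.Ramp("a3s", 50.0, 14.0, 10.0)])
        assert sim.ramp_parameter(p, sched, 40.0).sten.a3s == 10.0
        assert sim.ramp_parameter(p, sched, 55.0).sten.a3s == pytest.approx(12.0)
        assert sim.ramp_parameter(p, sched, 80.0).sten.a3s == 14.0
        assert p.sten.a3s == 10.0  # base untouched

    def test_unknown_path_rejected(self):
        p = ModelParams()
        sched = sim.PerturbationSchedule([sim.Ramp("nope", 0.0, 1.0)])
        with pytest.raises(KeyError):
            sched.validate(p)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            sim.Ramp("a3s", 0.0, 1.0, duration=0.0)


class TestPresets:
    @pytest.mark.parametrize("name", sim.PRESET_NAMES)
    def test_presets_are_runnable(self, name):
        p, sched = sim.perturbation_preset(name)
        p.validate()
        sched.validate(p)

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            sim.perturbation_preset("cytochalasin")

    def test_lata_silences_cen(self):
        p, _ = sim.perturbation_preset("lata")
        assert p.cen.sigma_c == 0.0
        assert p.cen.s_c == 0.0
        f_c, r_c = mc.resting_equilibrium(p.cen)
        assert f_c == 0.0

    def test_fig3_preset_carries_slow_inhibitor(self):
        p, _ = sim.perturbation_preset("fig3-wave-stopping")
        assert p.sten.eps_s == 0.03
        assert p.sten.u_b == 0.0


class TestRunAndReadout:
    def test_zero_duration_returns_initial_state_only(self):
        p = ModelParams()
        traj = sim.run(p, sim.GridSpec((16,)), duration=0.0, seed=0,
                       burn_in=1.0)
        assert len(traj.times) == 1
        assert traj.frames["R_S"].shape == (1, 16)

    def test_run_reproducible(self):
        p = ModelParams()
        g = sim.GridSpec((20, 20))
        t1 = sim.run(p, g, duration=6.0, save_interval=2.0, seed=3, burn_in=2.0)
        t2 = sim.run(p, g, duration=6.0, save_interval=2.0, seed=3, burn_in=2.0)
        assert np.array_equal(t1.frames["R_S"], t2.frames["R_S"])
        assert np.all(np.diff(t1.times) > 0)

    def test_readout_normalization_invertible(self):
        p = ModelParams()
        g = sim.GridSpec((20, 20))
        traj = sim.run(p, g, duration=10.0, save_interval=2.0, seed=3,
                       burn_in=2.0)
        movie = sim.readout(traj)
        lo, hi = movie.meta["norm_constants"]["R_S"]
        raw = movie.channel("R_S") * (hi - lo) + lo
        np.testing.assert_allclose(raw, traj.frames["R_S"], atol=1e-12)

    def test_readout_line_kymograph(self):
        p = ModelParams()
        g = sim.GridSpec((20, 20))
        traj = sim.run(p, g, duration=10.0, save_interval=2.0, seed=3,
                       burn_in=2.0)
        kymos = sim.readout(traj, line=((10.0, 0.0), (10.0, 19.0)))
        assert kymos["R_S"].shape == (20, len(traj.times))

    def test_empty_trajectory_rejected(self):
        p = ModelParams()
        traj = sim.run(p, sim.GridSpec((8,)), duration=0.0, seed=0, burn_in=0.0)
        traj.times = np.empty(0)
        with pytest.raises(ValueError):
            sim.readout(traj)


class TestFieldContracts:
    def test_global_inhibitor_is_spatially_uniform(self):
        # W_C diffuses fast enough that its spatial variation stays < 1%
        p = ModelParams()
        g = sim.GridSpec((48, 48))
        traj = sim.run(p, g, duration=60.0, save_interval=10.0, seed=11,
                       burn_in=30.0, record=("W_C",))
        for frame in traj.frames["W_C"]:
            assert frame.std() < 0.01 * max(frame.mean(), 1e-12)

    def test_decoupled_cen_stays_punctate(self):
        # with s_c = 0, CEN firings are spatially confined: the spatial
        # autocorrelation length of the activator stays below 3 grid steps
        p = ModelParams()
        p.cen.s_c = 0.0
        p.sten.u_b = 0.0
        g = sim.GridSpec((48, 48))
        traj = sim.run(p, g, duration=40.0, save_interval=2.0, seed=5,
                       burn_in=20.0, record=("F_C",))
        lengths = []
        for frame in traj.frames["F_C"]:
            f = frame - frame.mean()
            var = float((f * f).mean())
            if var < 1e-6:
                continue
            for shift in range(1, 8):
                c = float((f[:, shift:] * f[:, :-shift]).mean()) / var
                if c < np.exp(-1):
                    lengths.append(shift)
                    break
            else:
                lengths.append(8)
        assert lengths, "no active frames"
        assert np.mean(lengths) < 3.0
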