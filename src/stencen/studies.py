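"""Reference study protocols: the standard in-silico experiments.

Each function wires together the simulation, theory, and quantification
modules into one named computational experiment (wave stalling, acute
recruitment before/after comparisons, double-band line scans, estimator
recovery on synthetic movies).  Problem sizes default to desk-scale grids;
every protocol is deterministic given its seed.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional, Tuple

import numpy as np

from . import model_core as mc
from . import simulate as sim
from . import synthetic_data as sd
from . import wave_metrics as wm
from . import wave_theory as wt
from .params import ModelParams, STENParams

__all__ = [
    "stall_level_study",
    "triggered_wave_summary",
    "before_after_study",
    "racgef1_response_study",
    "lata_expansion_study",
    "double_band_study",
    "speed_recovery_study",
    "puncta_recovery_study",
    "before_after_recovery_study",
    "fraction_fastest_study",
    "offset_recovery_study",
]

# before/after comparisons need a stationary baseline; the slow STEN
# inhibitor (1/eps_s ~ 33 time units) sets the equilibration scale
EQUILIBRATION = 150.0


def stall_level_study(n: int = 3000, duration: float = 400.0) -> dict:
    """Free-running 1D wave stall level versus the analytic R_stop."""
    p, _ = sim.perturbation_preset("fig3-wave-stopping")
    res = wt.simulated_stall_level(p.sten, n=n, duration=duration)
    rs = wt.r_stop(p.sten)
    r_lo, r_hi = wt.bistable_window(p.sten)
    res.update({
        "r_stop_analytic": rs,
        "window": (r_lo, r_hi),
        "error_fraction_of_window": (res["stall_level"] - rs) / (r_hi - r_lo),
    })
    return res


def triggered_wave_summary(p_sten: STENParams, n: int = 1200,
                           duration: float = 250.0) -> Tuple[float, float]:
    """(front speed, range) of one deterministic triggered 1D wave."""
    tr = sim.front_trace_1d(p_sten, n=n, duration=duration)
    speed = wt.measure_front_speed(tr["positions"], tr["times"])
    if not tr["propagated"]:
        speed = 0.0
    return speed, tr["range"]


def _windowed_speed(stack: np.ndarray, save: float, low: float = 0.1,
                    high: float = 10.0) -> wm.SpeedReport:
    movie = wm.WaveMovie({"x": stack}, pixel_size=1.0, frame_interval=save)
    return wm.wave_speed(movie, low=low, high=high)


def before_after_study(preset: str, seed: int, grid: int = 64,
                       ramp_start: float = 120.0, duration: float = 300.0,
                       save: float = 2.0,
                       ) -> Dict[str, Tuple[wm.SpeedReport, wm.SpeedReport]]:
    """Stochastic 2D run of an acute-recruitment preset; paired speed/patch
    reports for both channels over the pre-ramp and post-ramp windows."""
    p, sched = sim.perturbation_preset(preset, ramp_start=ramp_start)
    traj = sim.run(p, sim.GridSpec((grid, grid)), duration=duration,
                   schedule=sched, save_interval=save, seed=seed,
                   burn_in=EQUILIBRATION, record=("R_S", "R_C"))
    movie = sim.readout(traj)
    n_pre = int(ramp_start / save)
    n_gap = int(30.0 / save)
    out = {}
    for ch in ("R_S", "R_C"):
        x = movie.channel(ch)
        out[ch] = (_windowed_speed(x[0:n_pre], save),
                   _windowed_speed(x[n_pre + n_gap:], save))
    return out


def racgef1_response_study(seed: int, grid: int = 64,
                           ramp_start: float = 100.0,
                           duration: float = 280.0) -> dict:
    """Spatially averaged STEN readout around constitutive Rac activation:
    transient rise, then sustained suppression below baseline."""
    p, sched = sim.perturbation_preset("racgef1", ramp_start=ramp_start)
    traj = sim.run(p, sim.GridSpec((grid, grid)), duration=duration,
                   schedule=sched, save_interval=2.0, seed=seed,
                   burn_in=EQUILIBRATION, record=("R_S",))
    t = traj.times
    mean_rs = traj.frames["R_S"].mean(axis=(1, 2))
    baseline = float(mean_rs[(t > 20) & (t < ramp_start)].mean())
    rise_win = (t >= ramp_start) & (t <= ramp_start + 20)
    late = mean_rs[t > ramp_start + 60]
    return {
        "baseline": baseline,
        "peak_within_20": float(mean_rs[rise_win].max()),
        "late_mean": float(late.mean()),
        "late_max": float(late.max()),
        "times": t,
        "mean_readout": mean_rs,
    }


def lata_expansion_study(seed: int, grid: int = 64,
                         ramp_start: float = 120.0,
                         duration: float = 300.0) -> dict:
    """With CEN silenced, lowering the STEN threshold still expands STEN
    activity (basal noise u_b alone drives the network)."""
    p, _ = sim.perturbation_preset("lata")
    sched = sim.PerturbationSchedule([sim.Ramp("a3s", ramp_start, 11.5)])
    traj = sim.run(p, sim.GridSpec((grid, grid)), duration=duration,
                   schedule=sched, save_interval=2.0, seed=seed,
                   burn_in=EQUILIBRATION, record=("F_S",))
    t = traj.times
    act = (traj.frames["F_S"] > 1.0).mean(axis=(1, 2))
    return {
        "activity_pre": float(act[(t > 20) & (t < ramp_start)].mean()),
        "activity_post": float(act[t > ramp_start + 30].mean()),
    }


def double_band_study(seeds=(3, 4), n: int = 400,
                      duration: float = 150.0) -> dict:
    """Triggered 1D coupled waves: front-aligned mean STEN/CEN readout
    profiles plus the trailing-band spatial autocorrelation length."""
    p = ModelParams()
    p.sten.u_b = 0.0  # deterministic trigger; CEN noise stays on
    grid = sim.GridSpec((n,))
    prof_s, prof_c, corr_lengths = [], [], []
    for seed in seeds:
        st = sim.trigger(sim.initial_state(p, grid, seed=seed), slice(0, 8), 2.0)
        traj = sim.run(p, grid, duration=duration, save_interval=1.0,
                       seed=seed, burn_in=0.0, initial=st,
                       record=("F_S", "R_S", "F_C", "R_C"))
        fs = traj.frames["F_S"]
        for i in range(len(traj.times)):
            pk = fs[i].max()
            if pk < 1.0:
                continue
            front = int(np.where(fs[i] > 0.5 * pk)[0].max())
            if front < 110 or front > n - 30:
                continue
            sm = wm.smooth_profile(traj.frames["R_C"][i], 5)
            w0 = front - 8
            lead = w0 + int(np.argmax(sm[w0:min(front + 12, n - 1)]))
            if lead - 100 < 0 or lead + 20 > n - 1:
                continue
            prof_s.append(traj.frames["R_S"][i, lead - 100:lead + 21])
            prof_c.append(traj.frames["R_C"][i, lead - 100:lead + 21])
            # punctate trailing band: F_C autocorrelation behind the front
            tail = traj.frames["F_C"][i, max(front - 90, 0):front - 10]
            f = tail - tail.mean()
            var = float((f * f).mean())
            if var > 1e-4:
                for shift in range(1, 9):
                    c = float((f[shift:] * f[:-shift]).mean()) / var
                    if c < np.exp(-1):
                        corr_lengths.append(shift)
                        break
                else:
                    corr_lengths.append(9)
    mean_s = np.mean(prof_s, axis=0)
    mean_c = np.mean(prof_c, axis=0)
    i_lead = 100  # alignment point
    return {
        "mean_sten": mean_s,
        "mean_cen": mean_c,
        "n_profiles": len(prof_s),
        "cen_lead_peak": float(mean_c[i_lead]),
        "cen_dip": float(mean_c[i_lead - 14:i_lead - 4].min()),
        "cen_trailing_band": float(mean_c[i_lead - 70:i_lead - 20].mean()),
        "cen_background": float(np.mean(mean_c[i_lead + 12:])),
        "sten_peak_offset": int(np.argmax(mean_s) - i_lead),
        "trailing_autocorr_length": float(np.mean(corr_lengths)),
    }


# ---------------------------------------------------------------------------
# estimator recovery on synthetic microscopy
# ---------------------------------------------------------------------------

def speed_recovery_study(seed: int) -> dict:
    spec = sd.SyntheticWaveSpec(speed=0.2, noise_sd=0.05, seed=seed)
    movie, truth = sd.synth_wave_movie(spec)
    rep = wm.wave_speed(movie, channel="sten", low=0.1, high=5.0,
                        smooth_sigma=1.5)
    return {"programmed": truth["speed"], "estimated": rep.mean_speed,
            "n_frames": movie.n_frames}


def puncta_recovery_study(seed: int, rate: float = 1e-4,
                          duration: float = 400.0) -> dict:
    movie, rec = sd.synth_puncta_movie(rate=rate, lifetime_mean=10.8,
                                       size=3.0, grid=(120, 120),
                                       duration=duration, seed=seed,
                                       pixel_size=1.0, frame_interval=1.0)
    lifes = wm.puncta_lifetime(movie)
    return {"programmed_mean": 10.8, "estimated_mean": float(np.mean(lifes)),
            "n_tracked": len(lifes), "n_events": len(rec)}


def before_after_recovery_study(seed: int) -> dict:
    spec = sd.SyntheticWaveSpec(speed=0.1, speed_after=0.2, event_time=300.0,
                                noise_sd=0.02, duration=600.0,
                                frame_interval=5.0, shape=(96, 256),
                                seed=seed)
    movie, _ = sd.synth_wave_movie(spec)
    before, after = wm.before_after_report(movie, event_frame=60,
                                           channel="sten", low=0.1, high=5.0,
                                           smooth_sigma=1.5)
    return {"programmed_ratio": 2.0,
            "estimated_ratio": after.mean_speed / before.mean_speed,
            "before": before.mean_speed, "after": after.mean_speed}


def fraction_fastest_study(seed: int) -> dict:
    spec = sd.SyntheticWaveSpec(speed=0.2, noise_sd=0.02, speed_jitter_sd=0.7,
                                seed=seed)
    movie, _ = sd.synth_wave_movie(spec)
    rep = wm.wave_speed(movie, channel="sten", low=0.1, high=5.0,
                        smooth_sigma=1.0)
    # one-sided normal tail above mean + 1 sd
    return {"fraction_fastest": rep.fraction_fastest,
            "normal_tail": 0.1587, "n": rep.accepted_count}


def offset_recovery_study(offset: float = 4.0, n_seeds: int = 100,
                          noise_sd: float = 0.2) -> dict:
    noiseless = []
    for off in (-4.0, -2.0, 0.0, 2.0, 4.0):
        spec = sd.SyntheticWaveSpec(channel_offset=off, noise_sd=0.0)
        a, b, _ = sd.synth_linescan_pair(spec)
        d = wm.peak_distance(a, b, spec.pixel_size, 1).distance
        noiseless.append((d - off) / spec.pixel_size)
    ds = []
    for seed in range(n_seeds):
        spec = sd.SyntheticWaveSpec(channel_offset=offset, noise_sd=noise_sd,
                                    seed=seed)
        a, b, _ = sd.synth_linescan_pair(spec)
        ds.append(wm.peak_distance(a, b, spec.pixel_size, 1).distance)
    return {
        "noiseless_max_error_px": float(np.max(np.abs(noiseless))),
        "noisy_bias_px": float((np.mean(ds) - offset) / spec.pixel_size),
        "pixel_size": spec.pixel_size,
        "n_seeds": n_seeds,
    }
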