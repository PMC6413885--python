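"""Synthetic two-channel basal-surface wave movies with ground truth.

No raw microscopy is publicly deposited for the study system this package
models, so every analysis stage is exercised on synthetic data that
emulates its geometry: a diffuse one-peak STEN band and a sharp two-peak
CEN band (leading peak brighter, intermediate-intensity dip) propagating at
a programmed speed, with short-lived trailing puncta and additive Gaussian
(optionally Poisson) noise.  Every generator returns machine-readable
ground truth next to the pixels, so each estimator has a closed-loop
recovery test.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .wave_metrics import WaveMovie

__all__ = [
    "SyntheticWaveSpec",
    "synth_linescan_pair",
    "synth_wave_movie",
    "synth_stopping_kymograph",
    "synth_puncta_movie",
    "preset_configs",
]


@dataclass
class SyntheticWaveSpec:
    """Parameters of a rendered wave movie (lengths in micron, times in s)."""

    speed: float = 0.2                 # um/s
    direction: Tuple[float, float] = (0.0, 1.0)   # unit vector (dy, dx)
    sten_band_width: float = 4.0       # Gaussian sigma of the STEN band
    cen_peak_width: float = 2.0        # sigma of each CEN peak
    cen_peak_separation: float = 12.0  # distance between the two CEN peaks
    cen_mid_dip_fraction: float = 0.35  # mid-band level relative to peak
    channel_offset: float = 0.0        # signed STEN-peak minus CEN-lead-peak
    puncta_rate: float = 0.0           # events / um^2 / s in the trailing zone
    puncta_lifetime_mean: float = 10.8  # s
    noise_sd: float = 0.0              # additive Gaussian, intensity units
    shot_noise: bool = False
    pixel_size: float = 0.25           # um / pixel
    frame_interval: float = 5.0        # s / frame
    duration: float = 300.0            # s
    shape: Tuple[int, int] = (96, 160)  # (Y, X) pixels
    amplitude: float = 1.0
    stop_time: Optional[float] = None  # speed ramps linearly to 0 at this time
    speed_jitter_sd: float = 0.0       # per-frame Gaussian jitter of the
                                       # frame-to-frame advance (length units)
    event_time: Optional[float] = None  # speed switches to speed_after here
    speed_after: Optional[float] = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("sten_band_width", "cen_peak_width", "cen_peak_separation",
                     "pixel_size", "frame_interval", "duration", "amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.cen_mid_dip_fraction < 1.0):
            raise ValueError("cen_mid_dip_fraction must be in (0, 1)")
        if self.speed < 0 or self.puncta_rate < 0 or self.noise_sd < 0:
            raise ValueError("speed, puncta_rate, noise_sd must be >= 0")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["direction"] = list(d["direction"])
        d["shape"] = list(d["shape"])
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticWaveSpec":
        d = json.loads(text)
        d["direction"] = tuple(d["direction"])
        d["shape"] = tuple(d["shape"])
        spec = cls(**d)
        spec.validate()
        return spec


def _band_profiles(u: np.ndarray, spec: SyntheticWaveSpec
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """STEN and CEN intensity vs signed distance u from the CEN leading peak
    (u > 0 is ahead of the wave)."""
    a = spec.amplitude
    sep = spec.cen_peak_separation
    # CEN: leading peak at u=0 (brighter), trailing peak at u=-sep (dimmer),
    # intermediate-intensity floor between them
    w = spec.cen_peak_width
    lead = a * np.exp(-0.5 * (u / w) ** 2)
    trail = 0.7 * a * np.exp(-0.5 * ((u + sep) / w) ** 2)
    # intermediate-intensity floor between the peaks (the dip); it starts
    # clear of the leading peak and merges into the trailing peak's flank
    mid = spec.cen_mid_dip_fraction * a * 0.7 * (
        (u < -2 * w) & (u > -sep)).astype(float)
    cen = np.maximum.reduce([lead, trail, mid])
    # STEN: single diffuse band centered channel_offset ahead of the CEN lead
    sten = a * np.exp(-0.5 * ((u - spec.channel_offset) / spec.sten_band_width) ** 2)
    return sten, cen


def synth_linescan_pair(spec: SyntheticWaveSpec, length: Optional[float] = None
                        ) -> Tuple[np.ndarray, np.ndarray, dict]:
    """One STEN/CEN line-scan pair across a wave, plus ground truth.

    Profiles run along the propagation direction (index increases forward).
    Ground truth ``offset`` is the programmed STEN-minus-CEN peak distance
    (positive = STEN peak ahead).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if length is None:
        length = spec.shape[1] * spec.pixel_size
    n = int(round(length / spec.pixel_size))
    x = (np.arange(n) - 0.65 * n) * spec.pixel_size  # wave placed past center
    sten, cen = _band_profiles(x, spec)
    if spec.noise_sd > 0:
        sten = sten + rng.normal(0, spec.noise_sd, n)
        cen = cen + rng.normal(0, spec.noise_sd, n)
    truth = {
        "offset": spec.channel_offset,
        "pixel_size": spec.pixel_size,
        "cen_lead_peak_index": float(np.argmin(np.abs(x))),
    }
    return sten, cen, truth


def _speed_at(spec: SyntheticWaveSpec, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    v = np.full_like(t, spec.speed, dtype=float)
    if spec.event_time is not None and spec.speed_after is not None:
        v = np.where(t >= spec.event_time, spec.speed_after, v)
    if spec.stop_time is not None:
        v = v * np.clip(1.0 - t / spec.stop_time, 0.0, 1.0)
    return v


def synth_wave_movie(spec: SyntheticWaveSpec) -> Tuple[WaveMovie, dict]:
    """Two-channel movie of a band translating at the programmed speed.

    The band is uniform transverse to ``direction``; trailing puncta are
    born at rate ``puncta_rate`` in the zone behind the CEN trailing peak,
    stay where born, and live exponentially distributed lifetimes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.shape
    n_frames = int(spec.duration / spec.frame_interval) + 1
    dy, dx = spec.direction
    norm = math.hypot(dy, dx)
    dy, dx = dy / norm, dx / norm
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    proj = (yy * dy + xx * dx) * spec.pixel_size   # um along direction

    # front starts 20% along the projected extent
    p_lo, p_hi = proj.min(), proj.max()
    start = p_lo + 0.2 * (p_hi - p_lo)
    ts = np.arange(n_frames) * spec.frame_interval
    # integrate (possibly ramping) speed for center positions
    advances = (0.5 * (_speed_at(spec, ts[1:]) + _speed_at(spec, ts[:-1]))
                * np.diff(ts))
    if spec.speed_jitter_sd > 0:
        advances = advances + rng.normal(0, spec.speed_jitter_sd,
                                         advances.shape)
    centers = start + np.concatenate([[0.0], np.cumsum(advances)])

    # puncta: Poisson births in the trailing zone each frame interval
    puncta: List[dict] = []
    trail_depth = 3 * spec.cen_peak_separation
    sten_stack = np.empty((n_frames, ny, nx))
    cen_stack = np.empty((n_frames, ny, nx))
    for i, (t, c) in enumerate(zip(ts, centers)):
        u = proj - c
        sten, cen = _band_profiles(u, spec)
        if spec.puncta_rate > 0:
            zone_area = trail_depth * (ny * spec.pixel_size if dx else nx * spec.pixel_size)
            lam = spec.puncta_rate * zone_area * spec.frame_interval
            for _ in range(rng.poisson(lam)):
                u_b = -spec.cen_peak_separation - rng.uniform(0, trail_depth)
                # place at projected position u_b, random transverse position
                if abs(dx) >= abs(dy):
                    col = (c + u_b) / spec.pixel_size / dx if dx else 0
                    row = rng.uniform(0, ny - 1)
                else:
                    row = (c + u_b) / spec.pixel_size / dy
                    col = rng.uniform(0, nx - 1)
                if 0 <= row < ny and 0 <= col < nx:
                    puncta.append({
                        "row": row, "col": col, "birth": t,
                        "death": t + rng.exponential(spec.puncta_lifetime_mean),
                    })
        for pt in puncta:
            if pt["birth"] <= t < pt["death"]:
                rr = (yy - pt["row"]) ** 2 + (xx - pt["col"]) ** 2
                cen += 0.9 * spec.amplitude * np.exp(-0.5 * rr / 1.5 ** 2)
        sten_stack[i] = sten
        cen_stack[i] = cen

    if spec.shot_noise:
        scale = 50.0 / spec.amplitude
        sten_stack = rng.poisson(np.maximum(sten_stack, 0) * scale) / scale
        cen_stack = rng.poisson(np.maximum(cen_stack, 0) * scale) / scale
    if spec.noise_sd > 0:
        sten_stack = sten_stack + rng.normal(0, spec.noise_sd, sten_stack.shape)
        cen_stack = cen_stack + rng.normal(0, spec.noise_sd, cen_stack.shape)

    movie = WaveMovie(
        channels={"sten": sten_stack, "cen": cen_stack},
        pixel_size=spec.pixel_size, frame_interval=spec.frame_interval,
        meta={"spec": spec.to_json()},
    )
    truth = {
        "speed": spec.speed,
        "centers": centers,
        "times": ts,
        "puncta": pd.DataFrame(puncta, columns=["row", "col", "birth", "death"]),
        "puncta_lifetime_mean": spec.puncta_lifetime_mean,
    }
    return movie, truth


def synth_stopping_kymograph(initial_speed: float, deceleration: float,
                             seed: int = 0, n_x: int = 300,
                             n_t: int = 200, dt: float = 1.0,
                             pixel_size: float = 1.0, width: float = 3.0,
                             noise_sd: float = 0.0, mirror: bool = False
                             ) -> Tuple[np.ndarray, dict]:
    """Space-x-time stripe of a decelerating front, plus the stop position.

    Front position ``x(t) = x0 + v0*t - decel*t^2/2`` until the speed hits
    zero; afterwards the stripe terminates.  With ``mirror=True`` the front
    runs in the -x direction from the far end.
    """
    if initial_speed < 0 or deceleration < 0:
        raise ValueError("initial_speed and deceleration must be >= 0")
    rng = np.random.default_rng(seed)
    x = np.arange(n_x) * pixel_size
    t = np.arange(n_t) * dt
    x0 = 0.1 * n_x * pixel_size
    if deceleration > 0:
        t_stop = initial_speed / deceleration
    else:
        t_stop = np.inf
    tt = np.minimum(t, t_stop)
    pos = x0 + initial_speed * tt - 0.5 * deceleration * tt ** 2
    alive = t <= t_stop
    kymo = np.zeros((n_x, n_t))
    for j in range(n_t):
        if alive[j]:
            kymo[:, j] = np.exp(-0.5 * ((x - pos[j]) / width) ** 2)
    if mirror:
        kymo = kymo[::-1]
        pos = (n_x - 1) * pixel_size - pos
    if noise_sd > 0:
        kymo = kymo + rng.normal(0, noise_sd, kymo.shape)
    x_stop = pos[-1] if np.isfinite(t_stop) else None
    truth = {"stop_position": x_stop, "stop_time": t_stop,
             "positions": pos, "times": t}
    return kymo, truth


def synth_puncta_movie(rate: float, lifetime_mean: float, size: float,
                       grid: Tuple[int, int], duration: float, seed: int = 0,
                       pixel_size: float = 1.0, frame_interval: float = 1.0,
                       noise_sd: float = 0.0,
                       ) -> Tuple[WaveMovie, pd.DataFrame]:
    """Spatio-temporal Poisson process of small bright discs.

    ``rate`` is events per unit area per unit time (length units); lifetimes
    are exponential with the given mean.  Returns the movie and per-punctum
    records (row, col, birth, death).
    """
    if rate < 0 or lifetime_mean <= 0 or size <= 0:
        raise ValueError("rate >= 0, lifetime_mean > 0, size > 0 required")
    rng = np.random.default_rng(seed)
    ny, nx = grid
    area = ny * nx * pixel_size ** 2
    n_events = rng.poisson(rate * area * duration)
    births = rng.uniform(0, duration, n_events)
    deaths = births + rng.exponential(lifetime_mean, n_events)
    rows = rng.uniform(0, ny - 1, n_events)
    cols = rng.uniform(0, nx - 1, n_events)
    records = pd.DataFrame({"row": rows, "col": cols,
                            "birth": births, "death": deaths})
    records = records.sort_values("birth").reset_index(drop=True)

    n_frames = int(duration / frame_interval) + 1
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    stack = np.zeros((n_frames, ny, nx))
    for i in range(n_frames):
        t = i * frame_interval
        live = (records.birth <= t) & (t < records.death)
        for _, pt in records[live].iterrows():
            rr = (yy - pt.row) ** 2 + (xx - pt.col) ** 2
            stack[i] += np.exp(-0.5 * rr / (size / 2.0) ** 2)
    if noise_sd > 0:
        stack = stack + rng.normal(0, noise_sd, stack.shape)
    movie = WaveMovie(channels={"puncta": stack}, pixel_size=pixel_size,
                      frame_interval=frame_interval)
    return movie, records


def preset_configs() -> Dict[str, object]:
    """Versioned named fixtures for the analysis pipelines.

    Synthetic-movie fixtures plus the model perturbation presets (the
    latter as (ModelParams, PerturbationSchedule) pairs).
    """
    from .simulate import PRESET_NAMES, perturbation_preset

    out: Dict[str, object] = {
        "fig1-linescan": SyntheticWaveSpec(
            channel_offset=-2.0, noise_sd=0.05, seed=11),
        "fig2-movie": SyntheticWaveSpec(
            speed=0.2, puncta_rate=0.002, noise_sd=0.05,
            frame_interval=2.0, duration=200.0, seed=12),
        "fig3-kymo": {"initial_speed": 1.5, "deceleration": 0.01, "seed": 13},
    }
    for name in PRESET_NAMES:
        out[f"model-{name}"] = perturbation_preset(name)
    return out
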