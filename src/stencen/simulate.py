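"""Stochastic reaction-diffusion integration of the coupled STEN-CEN system.

The six fields (F_S, R_S, F_C, R_C, Z_C, W_C) evolve on a 1D or 2D grid by
explicit Euler-Maruyama: reaction rates from :mod:`stencen.model_core`,
diffusion by the central-difference Laplacian, and per-site independent
Gaussian increments with standard deviation ``sigma_N(Z,W)*sqrt(dt)`` on
F_S and ``sigma_c*sqrt(dt)`` on F_C.  Fields are floored at zero after each
step (concentrations).

The global negative-feedback species W_C carries a diffusivity far above
the explicit stability bound; its diffusion substep is applied exactly in
the eigenbasis of the same central-difference stencil (DCT for no-flux,
FFT for periodic), which is unconditionally stable and keeps the time step
set by the ordinary fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.fft

from . import model_core
from .params import ModelParams, STENParams

__all__ = [
    "GridSpec",
    "FieldState",
    "Ramp",
    "PerturbationSchedule",
    "Trajectory",
    "Disc",
    "laplacian",
    "stability_limit",
    "default_dt",
    "initial_state",
    "step",
    "trigger",
    "ramp_parameter",
    "perturbation_preset",
    "PRESET_NAMES",
    "run",
    "readout",
    "front_trace_1d",
]

FIELD_NAMES = ("F_S", "R_S", "F_C", "R_C", "Z_C", "W_C")


@dataclass
class GridSpec:
    """Simulation grid: shape ``(n_x,)`` or ``(n_y, n_x)``, step, boundary."""

    shape: Tuple[int, ...]
    spacing: float = 1.0
    boundary: str = "no-flux"

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if not all(s > 0 for s in self.shape) or len(self.shape) not in (1, 2):
            raise ValueError(f"bad grid shape {self.shape}")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.boundary not in ("no-flux", "periodic"):
            raise ValueError(f"unknown boundary {self.boundary!r}")

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def n_sites(self) -> int:
        return int(np.prod(self.shape))


def laplacian(field: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Central-difference Laplacian (3-point in 1D, 5-point in 2D)."""
    f = np.asarray(field, dtype=float)
    if f.shape != grid.shape:
        raise ValueError(f"field shape {f.shape} != grid shape {grid.shape}")
    h2 = grid.spacing ** 2
    if grid.boundary == "periodic":
        out = -2 * grid.ndim * f
        for ax in range(grid.ndim):
            out = out + np.roll(f, 1, axis=ax) + np.roll(f, -1, axis=ax)
        return out / h2
    # no-flux: zero-gradient ghost nodes (f[-1] := f[0], f[n] := f[n-1]);
    # this half-sample reflection conserves mass and is the stencil the
    # DCT-II spectral substep diagonalizes
    out = np.zeros_like(f)
    for ax in range(grid.ndim):
        n = f.shape[ax]
        fp = np.concatenate([f.take(range(1, n), axis=ax),
                             f.take([n - 1], axis=ax)], axis=ax)
        fm = np.concatenate([f.take([0], axis=ax),
                             f.take(range(0, n - 1), axis=ax)], axis=ax)
        out += fp + fm - 2 * f
    return out / h2


def stability_limit(p: ModelParams, grid: GridSpec) -> float:
    """Largest stable dt for the explicitly diffused fields."""
    d_max = max(p.sten.d_fs, p.sten.d_rs, p.cen.d_fc, p.cen.d_rc,
                p.feedback.d_zc)
    if d_max == 0:
        return np.inf
    return grid.spacing ** 2 / (4.0 * d_max)


def default_dt(p: ModelParams, grid: GridSpec) -> float:
    """Shipped default: 40% of the explicit stability bound."""
    lim = stability_limit(p, grid)
    return 0.4 * lim if np.isfinite(lim) else 0.01


@dataclass
class FieldState:
    """The six spatial fields at one time plus the RNG for reproducibility."""

    t: float
    F_S: np.ndarray
    R_S: np.ndarray
    F_C: np.ndarray
    R_C: np.ndarray
    Z_C: np.ndarray
    W_C: np.ndarray
    rng: np.random.Generator

    def copy(self) -> "FieldState":
        rng = np.random.default_rng()
        rng.bit_generator.state = self.rng.bit_generator.state
        return FieldState(self.t, *(getattr(self, n).copy() for n in FIELD_NAMES), rng)

    def check_finite(self) -> None:
        for n in FIELD_NAMES:
            if not np.all(np.isfinite(getattr(self, n))):
                raise FloatingPointError(f"non-finite values in {n}")


def initial_state(p: ModelParams, grid: GridSpec, seed: int = 0) -> FieldState:
    """Deterministic resting state: both modules and feedback at equilibrium."""
    f_s, r_s = model_core.resting_equilibrium(p.sten)
    f_c, r_c = model_core.resting_equilibrium(p.cen)
    z = p.feedback.p2 / p.feedback.p1 * f_c if p.feedback.p1 > 0 else 0.0
    w = p.feedback.p4 / p.feedback.p3 * f_c if p.feedback.p3 > 0 else 0.0
    full = lambda v: np.full(grid.shape, v, dtype=float)
    return FieldState(0.0, full(f_s), full(r_s), full(f_c), full(r_c),
                      full(z), full(w), np.random.default_rng(seed))


# -- exact diffusion substep in the stencil eigenbasis ----------------------

def _spectral_eigenvalues(grid: GridSpec) -> np.ndarray:
    h2 = grid.spacing ** 2
    eigs = []
    for n in grid.shape:
        m = np.arange(n)
        if grid.boundary == "periodic":
            lam = (2 * np.cos(2 * np.pi * m / n) - 2) / h2
        else:
            lam = (2 * np.cos(np.pi * m / n) - 2) / h2
        eigs.append(lam)
    if grid.ndim == 1:
        return eigs[0]
    return eigs[0][:, None] + eigs[1][None, :]


def _diffuse_exact(f: np.ndarray, d: float, dt: float, grid: GridSpec,
                   cache: dict) -> np.ndarray:
    key = (d, dt)
    if key not in cache:
        cache[key] = np.exp(d * dt * _spectral_eigenvalues(grid))
    mult = cache[key]
    if grid.boundary == "periodic":
        return np.real(scipy.fft.ifftn(scipy.fft.fftn(f) * mult))
    coef = scipy.fft.dctn(f, type=2, norm="ortho")
    return scipy.fft.idctn(coef * mult, type=2, norm="ortho")


def step(state: FieldState, p: ModelParams, dt: float, grid: GridSpec,
         _cache: Optional[dict] = None) -> FieldState:
    """One Euler-Maruyama step; returns a new FieldState at ``t + dt``.

    Enforces the explicit stability bound for the ordinary fields; the
    large-diffusivity W_C substep is exact (spectral) and unconditional.
    Advancing two states with identical RNG state is bit-reproducible.
    """
    lim = stability_limit(p, grid)
    if dt > lim * (1 + 1e-12):
        raise ValueError(f"dt={dt} violates stability bound {lim}")
    state.check_finite()
    if _cache is None:
        _cache = {}
    h2 = grid.spacing ** 2
    F_S, R_S, F_C, R_C, Z_C, W_C = (getattr(state, n) for n in FIELD_NAMES)

    s_in = model_core.coupling_input(R_S, p.cen, p.sten.r0)
    dfs, drs = model_core.sten_rates(F_S, R_S, 0.0, p.sten)
    dfc, drc = model_core.cen_rates(F_C, R_C, s_in, p.cen)
    dz, dw = model_core.feedback_rates(Z_C, W_C, F_C, p.feedback)

    sig_n = model_core.noise_sigma(Z_C, W_C, p.sten)
    sqdt = np.sqrt(dt)
    rng = state.rng
    noise_s = sig_n * rng.standard_normal(grid.shape) * sqdt
    noise_c = p.cen.sigma_c * rng.standard_normal(grid.shape) * sqdt

    new_F_S = F_S + dt * (p.sten.d_fs * laplacian(F_S, grid) + dfs) + noise_s
    new_R_S = R_S + dt * (p.sten.d_rs * laplacian(R_S, grid) + drs)
    new_F_C = F_C + dt * (p.cen.d_fc * laplacian(F_C, grid) + dfc) + noise_c
    new_R_C = R_C + dt * (p.cen.d_rc * laplacian(R_C, grid) + drc)
    new_Z_C = Z_C + dt * (p.feedback.d_zc * laplacian(Z_C, grid) + dz)
    new_W_C = W_C + dt * dw
    if p.feedback.d_wc > 0:
        new_W_C = _diffuse_exact(new_W_C, p.feedback.d_wc, dt, grid, _cache)

    for arr in (new_F_S, new_F_C, new_Z_C, new_W_C):
        np.maximum(arr, 0.0, out=arr)

    return FieldState(state.t + dt, new_F_S, new_R_S, new_F_C, new_R_C,
                      new_Z_C, new_W_C, rng)


@dataclass
class Disc:
    """Disc-shaped trigger region (2D): center in grid indices, radius."""

    center: Tuple[float, float]
    radius: float


def trigger(state: FieldState, location, amplitude: float) -> FieldState:
    """Add ``amplitude`` to F_S over the given region; all else unchanged."""
    new = state.copy()
    shape = new.F_S.shape
    if isinstance(location, Disc):
        if len(shape) != 2:
            raise ValueError("disc trigger requires a 2D grid")
        cy, cx = location.center
        if not (0 <= cy < shape[0] and 0 <= cx < shape[1]):
            raise IndexError(f"disc center {location.center} outside grid {shape}")
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= location.radius ** 2
        new.F_S[mask] += amplitude
    elif isinstance(location, slice):
        new.F_S[location] += amplitude
    else:
        idx = (int(location),) if np.isscalar(location) else tuple(int(i) for i in location)
        for i, n in zip(idx, shape):
            if not (0 <= i < n):
                raise IndexError(f"trigger index {idx} outside grid {shape}")
        new.F_S[idx] += amplitude
    return new


@dataclass
class Ramp:
    """Linear ramp of one parameter: pre-ramp value -> target over duration."""

    path: str
    start: float
    target: float
    duration: float = 10.0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("ramp duration must be > 0")


@dataclass
class PerturbationSchedule:
    ramps: List[Ramp] = field(default_factory=list)

    def validate(self, p: ModelParams) -> None:
        for r in self.ramps:
            p.get(r.path)  # raises KeyError on unknown path


def ramp_parameter(p: ModelParams, schedule: Optional[PerturbationSchedule],
                   t: float) -> ModelParams:
    """Parameters at time ``t``: linear interpolation inside each ramp."""
    if schedule is None or not schedule.ramps:
        return p
    out = p.copy()
    for r in schedule.ramps:
        base = p.get(r.path)
        frac = np.clip((t - r.start) / r.duration, 0.0, 1.0)
        out.set(r.path, base + frac * (r.target - base))
    return out


PRESET_NAMES = ("inp54p", "ras", "pkba", "racgef1", "lata",
                "fig3-wave-stopping")


def perturbation_preset(name: str, ramp_start: float = 100.0,
                        ) -> Tuple[ModelParams, PerturbationSchedule]:
    """Runnable configuration for a named acute-recruitment experiment.

    Magnitudes are calibrated so each preset reproduces its qualitative
    direction with margin; the recruitment itself is a 10-time-unit linear
    parameter ramp starting at ``ramp_start``.
    """
    p = ModelParams()
    sched = PerturbationSchedule()
    if name == "inp54p":
        # PIP2 depletion: strong increase of STEN positive feedback
        sched.ramps.append(Ramp("a3s", ramp_start, 11.5))
    elif name == "ras":
        # modest Ras activation: small increase of STEN positive feedback
        sched.ramps.append(Ramp("a3s", ramp_start, 10.5))
    elif name == "pkba":
        # raises STEN threshold (inhibitor-nullcline slope) and lowers CEN's
        sched.ramps.append(Ramp("c1s", ramp_start, 13.0))
        sched.ramps.append(Ramp("a3c", ramp_start, 12.0))
    elif name == "racgef1":
        # drives CEN to a high stable state: strong CEN positive feedback,
        # weaker activator decay, shallower inhibitor nullcline
        sched.ramps.append(Ramp("a3c", ramp_start, 16.0))
        sched.ramps.append(Ramp("a1c", ramp_start, 0.6))
        sched.ramps.append(Ramp("c1c", ramp_start, 2.0))
    elif name == "lata":
        # actin polymerization blocked: CEN silent, only u_b drives STEN
        p.cen.sigma_c = 0.0
        p.cen.a5c = 0.0
        p.cen.s_c = 0.0
    elif name == "fig3-wave-stopping":
        # deterministic 1D wave-stopping configuration
        p.sten.eps_s = 0.03
        p.sten.u_b = 0.0
        p.cen.sigma_c = 0.0
        p.cen.s_c = 0.0
    else:
        raise KeyError(f"unknown preset {name!r}; known: {PRESET_NAMES}")
    p.validate()
    sched.validate(p)
    return p, sched


@dataclass
class Trajectory:
    """Saved frames of selected fields at monotone save times."""

    times: np.ndarray
    frames: Dict[str, np.ndarray]  # name -> (T, *shape)
    grid: GridSpec
    params: ModelParams
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)
    final_state: Optional[FieldState] = None

    def __post_init__(self):
        t = np.asarray(self.times, float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("save times must be strictly increasing")


def run(p: ModelParams, grid: GridSpec, duration: float,
        schedule: Optional[PerturbationSchedule] = None,
        save_interval: float = 2.0, seed: int = 0,
        burn_in: float = 20.0, dt: Optional[float] = None,
        record: Sequence[str] = ("F_S", "R_S", "F_C", "R_C"),
        initial: Optional[FieldState] = None,
        progress: bool = False) -> Trajectory:
    """Integrate the full coupled system and save frames.

    The state starts at the deterministic resting equilibrium and burns in
    for ``burn_in`` time units before t=0; ramps and save times are relative
    to the post-burn-in origin.  Fully reproducible from (config, seed).
    """
    p.validate()
    if schedule is not None:
        schedule.validate(p)
    for name in record:
        if name not in FIELD_NAMES:
            raise KeyError(f"unknown field {name!r}")
    if dt is None:
        dt = default_dt(p, grid)
    state = initial if initial is not None else initial_state(p, grid, seed)
    cache: dict = {}

    times: List[float] = []
    frames: Dict[str, List[np.ndarray]] = {n: [] for n in record}

    def save(t: float) -> None:
        times.append(t)
        for n in record:
            frames[n].append(getattr(state, n).copy())

    n_burn = int(round(burn_in / dt))
    for _ in range(n_burn):
        state = step(state, p, dt, grid, cache)
    state.t = 0.0

    save(0.0)
    if duration > 0:
        next_save = save_interval
        n_steps = int(round(duration / dt))
        for i in range(n_steps):
            pt = ramp_parameter(p, schedule, state.t)
            state = step(state, pt, dt, grid, cache)
            if state.t >= next_save - 1e-9:
                save(state.t)
                next_save += save_interval
            if progress and i % max(1, n_steps // 20) == 0:
                print(f"  t={state.t:8.1f} / {duration}", flush=True)

    return Trajectory(
        times=np.array(times),
        frames={n: np.stack(v) for n, v in frames.items()},
        grid=grid, params=p, seed=seed,
        meta={"dt": dt, "burn_in": burn_in, "save_interval": save_interval},
        final_state=state,
    )


def readout(traj: Trajectory, line: Optional[Tuple] = None,
            norm_constants: Optional[Dict[str, Tuple[float, float]]] = None):
    """Normalized inhibitor readouts (R_S = STEN channel, R_C = CEN channel).

    Min-max normalization uses fixed per-configuration constants recorded in
    the metadata (invertible), so before/after comparisons stay meaningful.
    With ``line=((r0, c0), (r1, c1))`` returns a dict of space-x-time
    kymograph matrices instead of a movie.
    """
    from .wave_metrics import WaveMovie, kymograph as _kymo

    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    for ch in ("R_S", "R_C"):
        if ch not in traj.frames:
            raise ValueError(f"trajectory lacks {ch}; record it in run()")
    consts = {}
    stacks = {}
    for ch in ("R_S", "R_C"):
        raw = traj.frames[ch]
        if norm_constants and ch in norm_constants:
            lo, hi = norm_constants[ch]
        else:
            lo, hi = float(raw.min()), float(raw.max())
            if hi <= lo:
                hi = lo + 1.0
        consts[ch] = (lo, hi)
        stacks[ch] = (raw - lo) / (hi - lo)
    frame_interval = float(np.median(np.diff(traj.times))) if len(traj.times) > 1 else 1.0
    if line is not None:
        mov = WaveMovie(
            channels={ch: stacks[ch] for ch in stacks},
            pixel_size=traj.grid.spacing, frame_interval=frame_interval,
            meta={"norm_constants": consts},
        )
        return {ch: _kymo(mov, line, channel=ch) for ch in stacks}
    return WaveMovie(
        channels=stacks, pixel_size=traj.grid.spacing,
        frame_interval=frame_interval,
        meta={"norm_constants": consts, "fields": ("R_S", "R_C")},
    )


# ---------------------------------------------------------------------------
# deterministic STEN-only 1D runs for the wave-theory module
# ---------------------------------------------------------------------------

def front_trace_1d(p_sten: STENParams, r0: Optional[float] = None,
                   n: int = 1500, spacing: float = 1.0,
                   duration: float = 300.0, clamp_inhibitor: bool = False,
                   trigger_width: int = 8, trigger_amplitude: float = 2.0,
                   record_inhibitor: bool = False,
                   sample_every: float = 0.25) -> dict:
    """Trigger a deterministic 1D STEN pulse and track its front.

    The inhibitor field starts at ``r0`` (resting level if None) and either
    evolves freely or stays clamped.  Returns front positions/times (half-
    maximum crossing, linearly interpolated), the pulse range (distance from
    the trigger to the last site whose peak reached 10% of the global peak),
    and optionally the inhibitor level at the front.
    """
    p = dataclasses.replace(p_sten, u_b=0.0)
    f_star, r_star = model_core.resting_equilibrium(p)
    if r0 is None:
        r0 = r_star
    h = spacing
    d_max = p.d_fs if clamp_inhibitor else max(p.d_fs, p.d_rs)
    dt = 0.4 * h * h / (4.0 * d_max)
    F = np.full(n, f_star)
    R = np.full(n, float(r0))
    F[:trigger_width] += trigger_amplitude

    grid = GridSpec((n,), spacing=h, boundary="no-flux")
    times: List[float] = []
    positions: List[float] = []
    r_front: List[float] = []
    site_peak = F.copy()
    t = 0.0
    n_steps = int(duration / dt)
    rec_every = max(1, int(sample_every / dt))
    global_peak = F.max()
    fired = False

    for i in range(n_steps):
        dF = p.d_fs * laplacian(F, grid) + model_core.activator_rate(F, R, p)
        F2 = F + dt * dF
        if not clamp_inhibitor:
            dR = p.d_rs * laplacian(R, grid) + p.eps_s * (-R + p.c1s * F)
            R = R + dt * dR
        F = np.maximum(F2, 0.0)
        t += dt
        np.maximum(site_peak, F, out=site_peak)
        if i % rec_every == 0:
            pk = float(F.max())
            global_peak = max(global_peak, pk)
            amp = pk - f_star
            alive = amp > 0.25 * (global_peak - f_star) and pk > 0.5
            if alive:
                half = f_star + 0.5 * amp
                above = np.where(F > half)[0]
                pos_i = int(above.max())
                if pos_i + 1 < n and F[pos_i] > F[pos_i + 1]:
                    frac = (F[pos_i] - half) / (F[pos_i] - F[pos_i + 1])
                    pos = pos_i + min(max(frac, 0.0), 1.0)
                else:
                    pos = float(pos_i)
                if pos_i > trigger_width + 5:
                    fired = True
                times.append(t)
                positions.append(pos * h)
                if record_inhibitor:
                    r_front.append(float(np.interp(pos, np.arange(n), R)))
                if pos_i >= n - 3:
                    break  # reached the boundary
            elif fired or t > 30.0:
                break  # pulse has collapsed (or never launched)

    thresh = f_star + 0.1 * (global_peak - f_star)
    reached = np.where(site_peak >= thresh)[0]
    rng = float((reached.max() - trigger_width) * h) if reached.size else 0.0
    propagated = bool(positions and positions[-1] / h > trigger_width + 20)
    return {
        "times": times,
        "positions": positions,
        "r_front": r_front,
        "range": max(rng, 0.0),
        "propagated": propagated,
        "global_peak": global_peak,
        "rest": f_star,
        "final_F": F,
        "final_R": R,
    }
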