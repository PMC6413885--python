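"""Phase-plane and singular-perturbation wave theory.

In the singular limit (slow inhibitor, ``eps -> 0``) the speed of an
excitable front propagating into a region at inhibition level ``R0`` is
proportional to the net signed area under the cubic activator nullcline
between the outer activator roots at that level,

    A(R0) = integral_{F-}^{F+} f(F, R0) dF .

A(R0) decreases with R0; the level ``R_stop`` where it vanishes is the
Maxwell-type stopping condition: fronts advance below it, retreat above it,
and a wave that keeps raising the inhibition ahead of itself stalls when the
pre-front level reaches ``R_stop``.  The firing threshold is the gap
``th = R0 - R_min`` between the resting inhibition and the nullcline's fold
minimum; lower threshold means faster, longer-ranged waves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from . import model_core
from .params import ExcitableParams

__all__ = [
    "PhasePlaneReport",
    "threshold_level",
    "net_area",
    "r_stop",
    "bistable_window",
    "molecular_dispersion",
    "dispersion_predicts_stopping",
    "phase_plane_report",
    "speed_threshold_scan",
    "measure_front_speed",
    "simulated_stall_level",
]


@dataclass
class PhasePlaneReport:
    """Sampled phase-plane geometry plus the net-area stopping analysis."""

    activator_nullcline: np.ndarray  # (n, 2) [F, R]
    inhibitor_nullcline: np.ndarray  # (n, 2) [F, R]
    equilibrium: Tuple[float, float]
    cubic_minimum: Tuple[float, float]
    cubic_maximum: Tuple[float, float]
    threshold: float
    net_area_curve: np.ndarray  # (m, 2) [R0, A]
    r_stop: float
    speed_class: str = "excitable-waves"


class OutOfWindowError(ValueError):
    """Inhibitor level outside the three-root (bistable) window."""


def bistable_window(p: ExcitableParams) -> Tuple[float, float]:
    """(R_min, R_max) inhibitor range where the activator has three roots."""
    (f_min, r_min), (f_max, r_max) = model_core.nullcline_fold(p)
    return r_min, r_max


def threshold_level(p: ExcitableParams, r0: Optional[float] = None) -> float:
    """Signed threshold ``th = r0 - R_min`` (fold minimum of the nullcline).

    ``r0`` defaults to the resting equilibrium inhibition.  Larger values
    mean a harder-to-excite, slower-wave configuration.  Raises
    ``ValueError`` when the nullcline has no fold (not excitable).
    """
    (f_min, r_min), _ = model_core.nullcline_fold(p)
    if r0 is None:
        r0 = model_core.resting_equilibrium(p)[1]
    return float(r0 - r_min)


def net_area(r0: float, p: ExcitableParams) -> float:
    """Signed area under the activator rate between its outer roots at r0."""
    roots = model_core.nullcline_roots(r0, p)
    if len(roots) < 3:
        raise OutOfWindowError(
            f"inhibitor level {r0} outside the bistable window (roots: {roots})")
    f_lo, f_hi = roots[0], roots[2]
    val, _ = quad(lambda f: float(model_core.activator_rate(f, r0, p)),
                  f_lo, f_hi, epsabs=1e-10, limit=200)
    return float(val)


def r_stop(p: ExcitableParams) -> float:
    """Inhibition level at which the net area vanishes (wave stopping)."""
    r_lo, r_hi = bistable_window(p)
    pad = 1e-6 * (r_hi - r_lo)
    a, b = r_lo + pad, r_hi - pad
    fa, fb = net_area(a, p), net_area(b, p)
    if fa * fb > 0:
        raise OutOfWindowError("net area does not change sign inside the window")
    return float(brentq(lambda r: net_area(r, p), a, b, xtol=1e-9))


def molecular_dispersion(diff_coef: float, lifetime: float) -> float:
    """Dispersion length ``sqrt(D * tau)`` of a diffusing, decaying species."""
    if diff_coef < 0 or lifetime < 0:
        raise ValueError("diffusion coefficient and lifetime must be >= 0")
    return math.sqrt(diff_coef * lifetime)


def dispersion_predicts_stopping(p) -> bool:
    """Finite-range predicate: inhibitor must out-disperse the activator.

    Lifetime convention: activator ``1/a1s`` (leading-order self-decay),
    inhibitor ``1/eps_s`` (relaxation rate of the inhibitor).
    """
    sten = p.sten if hasattr(p, "sten") else p
    disp_act = molecular_dispersion(sten.d_fs, 1.0 / sten.a1s)
    disp_inh = molecular_dispersion(sten.d_rs, 1.0 / sten.eps_s)
    return disp_inh > disp_act


def phase_plane_report(p: ExcitableParams, n_samples: int = 400,
                       n_area: int = 60) -> PhasePlaneReport:
    """Full phase-plane summary: nullclines, threshold, A(R0), R_stop."""
    (f_min, r_min), (f_maxp, r_max) = model_core.nullcline_fold(p)
    f_star, r_star = model_core.resting_equilibrium(p)
    f_hi = model_core._f_max(p)
    fs = np.geomspace(max(f_star / 10, 1e-4), f_hi, n_samples)
    act = np.column_stack([fs, model_core.activator_nullcline(fs, p)])
    inh = np.column_stack([fs, p.c1 * fs])
    pad = 1e-4 * (r_max - r_min)
    r0s = np.linspace(r_min + pad, r_max - pad, n_area)
    areas = np.array([net_area(r, p) for r in r0s])
    rs = r_stop(p)
    th = r_star - r_min
    if th <= 0:
        speed_class = "synchronous-oscillation"
    elif r_star >= rs:
        speed_class = "no-spread"
    else:
        speed_class = "excitable-waves"
    return PhasePlaneReport(
        activator_nullcline=act,
        inhibitor_nullcline=inh,
        equilibrium=(f_star, r_star),
        cubic_minimum=(f_min, r_min),
        cubic_maximum=(f_maxp, r_max),
        threshold=th,
        net_area_curve=np.column_stack([r0s, areas]),
        r_stop=rs,
        speed_class=speed_class,
    )


# ---------------------------------------------------------------------------
# measured speeds from 1D simulations
# ---------------------------------------------------------------------------

def measure_front_speed(positions: Sequence[float], times: Sequence[float],
                        middle_fraction: float = 0.6) -> float:
    """Front speed by linear regression over the middle of the transit.

    Discards the first and last ``(1-middle_fraction)/2`` of the recorded
    transit to avoid startup and stall transients.
    """
    pos = np.asarray(positions, float)
    t = np.asarray(times, float)
    if len(pos) < 4:
        return 0.0
    n = len(pos)
    lo = int(n * (1 - middle_fraction) / 2)
    hi = n - lo
    if hi - lo < 2:
        lo, hi = 0, n
    slope = np.polyfit(t[lo:hi], pos[lo:hi], 1)[0]
    return float(max(slope, 0.0))


@dataclass
class ScanRow:
    r0: float
    speed: float
    range: float
    speed_class: str


def speed_threshold_scan(p: ExcitableParams, r0_grid: Sequence[float],
                         n: int = 1500, spacing: float = 1.0,
                         duration: float = 300.0,
                         clamp_inhibitor: bool = True,
                         progress: bool = False) -> List[ScanRow]:
    """Measured 1D front speed and range at each initial inhibition level.

    Runs deterministic triggered 1D simulations with the inhibitor field
    initialized at (or, if ``clamp_inhibitor``, frozen at) ``r0``.  Speed is
    the half-maximum front-position regression; range is the distance from
    the trigger to the last point whose pulse peak reached at least 10% of
    the global pulse peak.  Non-propagating entries report speed 0.
    """
    from .simulate import front_trace_1d  # local import to avoid cycle

    rows: List[ScanRow] = []
    rs = r_stop(p)
    for r0 in r0_grid:
        trace = front_trace_1d(p, r0=float(r0), n=n, spacing=spacing,
                               duration=duration,
                               clamp_inhibitor=clamp_inhibitor)
        speed = measure_front_speed(trace["positions"], trace["times"])
        rng = trace["range"]
        if trace["propagated"]:
            cls = "excitable-waves"
        elif float(r0) >= rs:
            cls = "no-spread"
        else:
            cls = "no-spread"
        if not trace["propagated"]:
            speed = 0.0
        rows.append(ScanRow(r0=float(r0), speed=speed, range=rng, speed_class=cls))
    return rows


def simulated_stall_level(p: ExcitableParams, n: int = 3000,
                          spacing: float = 1.0, duration: float = 400.0,
                          ) -> dict:
    """Stall inhibition level of a free-running decelerating 1D wave.

    Triggers a pulse, tracks the half-maximum front position and the
    inhibitor level at the front, and extrapolates the speed-versus-
    inhibition relation to zero speed.  In the singular regime (small eps)
    this estimate agrees with the analytic ``r_stop``.
    """
    from .simulate import front_trace_1d

    trace = front_trace_1d(p, r0=None, n=n, spacing=spacing, duration=duration,
                           record_inhibitor=True)
    t = np.asarray(trace["times"])
    pos = np.asarray(trace["positions"])
    r_front = np.asarray(trace["r_front"])
    if len(t) < 10:
        raise RuntimeError("wave did not launch; cannot measure stall level")
    v = np.gradient(pos, t)
    sel = (v > 0.05) & (t > 5)
    idx = np.where(sel)[0]
    if len(idx) < 10:
        raise RuntimeError("too few decelerating samples to extrapolate")
    tail = idx[len(idx) // 3:]
    slope, intercept = np.polyfit(r_front[tail], v[tail], 1)
    stall = -intercept / slope
    return {
        "stall_level": float(stall),
        "range": trace["range"],
        "n_samples": int(len(tail)),
    }
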