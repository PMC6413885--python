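"""Point-wise (reaction-only) dynamics and nullcline algebra.

Each excitable module is an activator-inhibitor pair

    dF/dt = -(a1 + a2*Reff)*F + a3*F^2/(a4^2 + F^2) + a5 (+ drive)
    dR/dt = eps*(-R + c1*F)

where for STEN the drive is the stochastic input ``u_n`` and ``Reff = R``,
and for CEN the coupling from STEN enters by offsetting the effective
inhibition, ``Reff = R - s_in``.  The activator nullcline is cubic-shaped:
for inhibitor levels between its local minimum and local maximum the
activator has three fixed points (rest, threshold, excited).  A resting
equilibrium on the descending left branch makes the module excitable.
"""

from __future__ import annotations

import math
from typing import List, Tuple

import numpy as np
from scipy.optimize import brentq

from .params import CENParams, ExcitableParams, STENParams

__all__ = [
    "sten_rates",
    "cen_rates",
    "feedback_rates",
    "coupling_input",
    "noise_sigma",
    "activator_rate",
    "activator_nullcline",
    "nullcline_roots",
    "nullcline_fold",
    "resting_equilibrium",
    "is_excitable",
]


def _check_finite(*values) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite input to reaction rate")


def activator_rate(f, r_eff, p: ExcitableParams):
    """Reaction rate of the activator at effective inhibition ``r_eff``."""
    f = np.asarray(f, dtype=float)
    return (-(p.a1 + p.a2 * r_eff) * f
            + p.a3 * f * f / (p.a4 * p.a4 + f * f) + p.a5)


def sten_rates(f_s, r_s, u_n, p: STENParams) -> Tuple[float, float]:
    """STEN reaction rates ``(dF_S/dt, dR_S/dt)`` (diffusion excluded)."""
    _check_finite(f_s, r_s, u_n)
    df = activator_rate(f_s, r_s, p) + u_n
    dr = p.eps_s * (-np.asarray(r_s, dtype=float) + p.c1s * f_s)
    return df, dr


def cen_rates(f_c, r_c, s_in, p: CENParams) -> Tuple[float, float]:
    """CEN reaction rates; ``s_in`` offsets the effective inhibition."""
    _check_finite(f_c, r_c, s_in)
    df = activator_rate(f_c, np.asarray(r_c, dtype=float) - s_in, p)
    dr = p.eps_c * (-np.asarray(r_c, dtype=float) + p.c1c * f_c)
    return df, dr


def feedback_rates(z_c, w_c, f_c, p) -> Tuple[float, float]:
    """Linear rates of the CEN-to-STEN feedback species (Z_C, W_C)."""
    _check_finite(z_c, w_c, f_c)
    dz = -p.p1 * np.asarray(z_c, dtype=float) + p.p2 * f_c
    dw = -p.p3 * np.asarray(w_c, dtype=float) + p.p4 * f_c
    return dz, dw


def coupling_input(r_s, p: CENParams, r0: float):
    """STEN-to-CEN coupling drive ``s_in = s_c * (R_S - r0)`` (may be < 0)."""
    return p.s_c * (np.asarray(r_s, dtype=float) - r0)


def noise_sigma(z_c, w_c, p: STENParams):
    """STEN noise standard deviation ``max(0, u_b + Z_C - W_C)``.

    The clamp at zero encodes that strong global inhibition silences
    stochastic triggering entirely.
    """
    return np.maximum(0.0, p.u_b + np.asarray(z_c, dtype=float) - w_c)


def activator_nullcline(f, p: ExcitableParams):
    """Inhibitor level R on the activator nullcline at activator level f > 0."""
    f = np.asarray(f, dtype=float)
    return (-p.a1 * f + p.a3 * f * f / (p.a4 * p.a4 + f * f) + p.a5) / (p.a2 * f)


_ROOT_TOL = 1e-9
_SCAN_RES = 1e-4


def _f_max(p: ExcitableParams) -> float:
    # beyond a3/a1 + a5/a1 + a4 the activator rate is strictly negative
    return (p.a3 + p.a5) / max(p.a1, 1e-12) + p.a4 + 1.0


def nullcline_roots(r: float, p: ExcitableParams, s_in: float = 0.0) -> List[float]:
    """Real nonnegative activator roots at fixed inhibitor level, ascending.

    Generic counts are 1 (mono-stable rest or excited) or 3 (bistable
    window); a tangency within tolerance may report 2.
    """
    if not math.isfinite(r):
        raise ValueError("inhibitor level must be finite")
    r_eff = r - s_in
    fmax = _f_max(p)
    # bracketing scan at fixed resolution, then polish with brentq
    n = int(fmax / _SCAN_RES) + 2
    # coarse-to-fine: a full 1e-4 scan is ~1e5 points, cheap enough
    fs = np.linspace(0.0, fmax, n)
    gs = activator_rate(fs, r_eff, p)
    roots: List[float] = []
    sign = np.sign(gs)
    flips = np.where(sign[:-1] * sign[1:] < 0)[0]
    for i in flips:
        roots.append(brentq(lambda f: float(activator_rate(f, r_eff, p)),
                            fs[i], fs[i + 1], xtol=_ROOT_TOL))
    # exact zeros on grid points (rare)
    for i in np.where(gs == 0.0)[0]:
        roots.append(float(fs[i]))
    roots = sorted(set(round(x, 12) for x in roots))
    # merge near-tangent duplicates
    merged: List[float] = []
    for x in roots:
        if merged and abs(x - merged[-1]) < 1e-9:
            continue
        merged.append(x)
    return merged


def nullcline_fold(p: ExcitableParams) -> Tuple[Tuple[float, float], Tuple[float, float]]:
    """Local minimum and maximum of the cubic activator nullcline.

    Returns ``((F_min, R_min), (F_max, R_max))``.  Raises ``ValueError``
    ("not excitable") when the nullcline has no fold.
    """
    fmax = _f_max(p)
    fs = np.linspace(1e-6, fmax, 400001)
    rn = activator_nullcline(fs, p)
    d = np.diff(rn)
    sign = np.sign(d)
    flips = np.where(sign[:-1] * sign[1:] < 0)[0]
    mins = [i for i in flips if d[i] < 0 < d[i + 1]]
    maxs = [i for i in flips if d[i] > 0 > d[i + 1]]
    if not mins or not maxs:
        raise ValueError("not excitable: activator nullcline has no fold")
    i_min, i_max = mins[0], maxs[0]

    def refine(i, lo_is_min):
        a, b = fs[max(i - 2, 0)], fs[min(i + 3, len(fs) - 1)]
        grid = np.linspace(a, b, 20001)
        vals = activator_nullcline(grid, p)
        j = np.argmin(vals) if lo_is_min else np.argmax(vals)
        return float(grid[j]), float(vals[j])

    return refine(i_min, True), refine(i_max, False)


def resting_equilibrium(p: ExcitableParams) -> Tuple[float, float]:
    """Resting fixed point (F*, R*) of the reaction-only system.

    Solves the intersection of the inhibitor nullcline ``R = c1*F`` with the
    activator nullcline on its left (descending) branch.
    """
    def h(f):
        return float(activator_rate(f, p.c1 * f, p))

    fmax = _f_max(p)
    fs = np.linspace(1e-9, fmax, 200001)
    hs = activator_rate(fs, p.c1 * fs, p)
    sign = np.sign(hs)
    flips = np.where(sign[:-1] * sign[1:] < 0)[0]
    if len(flips) == 0:
        if p.a5 == 0 and float(hs[0]) <= 0:
            return 0.0, 0.0  # silenced module: origin is the rest state
        raise ValueError("no equilibrium found")
    f_star = brentq(h, fs[flips[0]], fs[flips[0] + 1], xtol=1e-14)
    return float(f_star), float(p.c1 * f_star)


def is_excitable(p: ExcitableParams) -> bool:
    """True when the module has a unique, stable, left-branch rest state.

    Checks: the activator nullcline has a fold; there is exactly one
    equilibrium; it lies on the left branch (below the fold's F minimum);
    and its inhibition level sits inside or below the bistable window so a
    finite perturbation can fire.
    """
    try:
        (f_min, r_min), (f_max_, r_max) = nullcline_fold(p)
    except ValueError:
        return False
    # count equilibria
    fmax = _f_max(p)
    fs = np.linspace(1e-9, fmax, 200001)
    hs = activator_rate(fs, p.c1 * fs, p)
    sign = np.sign(hs)
    n_eq = int(np.sum(sign[:-1] * sign[1:] < 0))
    if n_eq != 1:
        return False
    f_star, r_star = resting_equilibrium(p)
    if f_star >= f_min:
        return False
    # rest inhibition must be inside the bistable window (else nothing to fire)
    return r_min < r_star < r_max
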