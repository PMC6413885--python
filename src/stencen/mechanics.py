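"""Level-set simulation of wave-driven cell-boundary motion.

The cell boundary is the zero level set of a signed distance function phi
(negative inside).  Wave activity sampled at boundary nodes is converted to
outward normal stress; total stress adds surface tension (against
curvature) and a proportional volume-conservation term:

    sigma_tot = protrusion_gain * activity
                - tension_coef * curvature
                - volume_gain * (area - reference_area) / reference_area

A Kelvin-Voigt-type viscoelastic law turns stress into membrane and cortex
velocities:

    xdot_mem = -(K/D) * x_cor + (1/D + 1/B) * sigma_tot
    xdot_cor = -(K/D) * x_cor + (1/D) * sigma_tot

with K the cortex elasticity, D the membrane viscosity and B the cytoplasm
viscosity.  ``xdot_mem`` drives upwind level-set advection; phi is
re-distanced every few steps to keep |grad phi| near 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from .simulate import GridSpec

__all__ = [
    "MechParams",
    "CellShape",
    "init_shape",
    "boundary_nodes",
    "shape_area",
    "boundary_curvature",
    "total_stress",
    "viscoelastic_step",
    "evolve",
    "run_morphology",
]

REINIT_EVERY = 10


@dataclass
class MechParams:
    """Viscoelastic and stress-composition constants (nondimensional)."""

    k_el: float = 1.0          # cortex elasticity K
    d_visc: float = 1.0        # membrane viscosity D
    b_visc: float = 2.0        # cytoplasm viscosity B
    tension_coef: float = 0.3
    volume_gain: float = 20.0
    protrusion_gain: float = 1.0

    def validate(self) -> None:
        for f_ in ("k_el", "d_visc", "b_visc", "tension_coef",
                   "volume_gain", "protrusion_gain"):
            if getattr(self, f_) <= 0:
                raise ValueError(f"{f_} must be > 0")


@dataclass
class CellShape:
    """Signed distance field plus per-boundary-node cortex displacement."""

    phi: np.ndarray
    grid: GridSpec
    x_cor: np.ndarray            # aligned with boundary_nodes(self)
    reference_area: float
    steps_since_reinit: int = 0

    def nodes(self) -> np.ndarray:
        return boundary_nodes(self.phi)


def boundary_nodes(phi: np.ndarray) -> np.ndarray:
    """Zero-contour nodes (row, col) in grid-index coordinates."""
    contours = measure.find_contours(phi, 0.0)
    if not contours:
        raise ValueError("empty boundary: no zero level set")
    return max(contours, key=len)


def shape_area(shape: CellShape) -> float:
    """Area enclosed by the zero contour (shoelace, sub-grid accurate)."""
    nodes = boundary_nodes(shape.phi)
    y, x = nodes[:, 0], nodes[:, 1]
    a = 0.5 * np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(a * shape.grid.spacing ** 2)


def init_shape(radius: float, grid: GridSpec) -> CellShape:
    """Disc-shaped cell centered on the grid; exact disc SDF."""
    if grid.ndim != 2:
        raise ValueError("mechanics requires a 2D grid")
    ny, nx = grid.shape
    h = grid.spacing
    if 2 * radius >= min(ny, nx) * h - 4 * h:
        raise ValueError(f"disc of radius {radius} does not fit grid {grid.shape}")
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    phi = np.hypot((yy - cy) * h, (xx - cx) * h) - radius
    shape = CellShape(phi=phi, grid=grid, x_cor=np.empty(0),
                      reference_area=float(np.pi) * radius ** 2)
    shape.x_cor = np.zeros(len(boundary_nodes(phi)))
    return shape


def boundary_curvature(shape: CellShape) -> np.ndarray:
    """Curvature div(grad phi / |grad phi|) sampled at boundary nodes.

    Positive for a convex (outward-bulging) boundary, 1/r on a disc.
    """
    h = shape.grid.spacing
    gy, gx = np.gradient(shape.phi, h)
    norm = np.hypot(gy, gx)
    norm = np.where(norm < 1e-9, 1e-9, norm)
    ky = np.gradient(gy / norm, h, axis=0)
    kx = np.gradient(gx / norm, h, axis=1)
    kappa = ky + kx
    nodes = boundary_nodes(shape.phi)
    return ndimage.map_coordinates(kappa, [nodes[:, 0], nodes[:, 1]], order=1)


def total_stress(shape: CellShape, activity: np.ndarray,
                 p: MechParams) -> np.ndarray:
    """Outward normal stress per boundary node."""
    p.validate()
    nodes = boundary_nodes(shape.phi)
    activity = np.asarray(activity, dtype=float)
    if activity.ndim == 0:
        activity = np.full(len(nodes), float(activity))
    if len(activity) != len(nodes):
        raise ValueError(
            f"activity has {len(activity)} values for {len(nodes)} boundary nodes")
    kappa = boundary_curvature(shape)
    area = shape_area(shape)
    vol_term = p.volume_gain * (area - shape.reference_area) / shape.reference_area
    return p.protrusion_gain * activity - p.tension_coef * kappa - vol_term


def viscoelastic_step(x_cor: np.ndarray, sigma_tot: np.ndarray,
                      p: MechParams, dt: float) -> Tuple[np.ndarray, np.ndarray]:
    """One explicit update of the membrane/cortex system.

    Returns (membrane normal velocity, new cortex displacement).  Steady
    state under constant stress: x_cor -> sigma/K, xdot_mem -> sigma/B.
    """
    x_cor = np.asarray(x_cor, dtype=float)
    sigma_tot = np.asarray(sigma_tot, dtype=float)
    if not (np.all(np.isfinite(x_cor)) and np.all(np.isfinite(sigma_tot))):
        raise ValueError("non-finite mechanics inputs")
    kd = p.k_el / p.d_visc
    v_mem = -kd * x_cor + (1.0 / p.d_visc + 1.0 / p.b_visc) * sigma_tot
    # x_cor relaxes linearly toward sigma/K; use the exact exponential update
    # (stable for any dt, exact under stress held constant over the step)
    x_inf = sigma_tot / p.k_el
    x_cor_new = x_inf + (x_cor - x_inf) * np.exp(-kd * dt)
    return v_mem, x_cor_new


def _reinitialize(phi: np.ndarray, h: float) -> np.ndarray:
    """Re-distance phi from its sign pattern (EDT with half-pixel offset)."""
    inside = phi < 0
    if not inside.any() or inside.all():
        return phi
    d_out = ndimage.distance_transform_edt(~inside)
    d_in = ndimage.distance_transform_edt(inside)
    return np.where(inside, -(d_in - 0.5), d_out - 0.5) * h


def evolve(shape: CellShape, v_n: np.ndarray, dt: float) -> CellShape:
    """Advect the boundary with per-node normal velocity ``v_n``.

    The node velocities are extended to the grid by nearest boundary node,
    then phi is advanced with a Godunov upwind |grad phi| scheme.  The
    cortex displacement rides along: after the move it is re-sampled onto
    the new boundary nodes from the nearest old node.
    """
    h = shape.grid.spacing
    v_n = np.asarray(v_n, dtype=float)
    nodes = boundary_nodes(shape.phi)
    if len(v_n) != len(nodes):
        raise ValueError("one velocity per boundary node required")
    vmax = float(np.max(np.abs(v_n))) if len(v_n) else 0.0
    if vmax * dt > 0.5 * h + 1e-12:
        raise ValueError(f"CFL violation: max|v|*dt = {vmax * dt:.3g} > 0.5*h")

    ny, nx = shape.phi.shape
    if vmax > 0:
        tree = cKDTree(nodes)
        yy, xx = np.mgrid[0:ny, 0:nx]
        _, idx = tree.query(np.column_stack([yy.ravel(), xx.ravel()]))
        v_ext = v_n[idx].reshape(ny, nx)
    else:
        v_ext = np.zeros_like(shape.phi)

    phi = shape.phi
    # Godunov upwind gradient magnitude
    dmx = np.diff(phi, axis=1, prepend=phi[:, :1]) / h
    dpx = np.diff(phi, axis=1, append=phi[:, -1:]) / h
    dmy = np.diff(phi, axis=0, prepend=phi[:1, :]) / h
    dpy = np.diff(phi, axis=0, append=phi[-1:, :]) / h
    # outward motion (v > 0): phi decreases; use appropriate one-sided stencils
    grad_plus = np.sqrt(np.maximum(dmx, 0) ** 2 + np.minimum(dpx, 0) ** 2 +
                        np.maximum(dmy, 0) ** 2 + np.minimum(dpy, 0) ** 2)
    grad_minus = np.sqrt(np.minimum(dmx, 0) ** 2 + np.maximum(dpx, 0) ** 2 +
                         np.minimum(dmy, 0) ** 2 + np.maximum(dpy, 0) ** 2)
    phi_new = phi - dt * (np.maximum(v_ext, 0) * grad_plus +
                          np.minimum(v_ext, 0) * grad_minus)

    count = shape.steps_since_reinit + 1
    if count >= REINIT_EVERY:
        phi_new = _reinitialize(phi_new, h)
        count = 0

    new_nodes = boundary_nodes(phi_new)
    if len(nodes):
        tree = cKDTree(nodes)
        _, idx = tree.query(new_nodes)
        x_cor_new = shape.x_cor[idx]
    else:
        x_cor_new = np.zeros(len(new_nodes))
    return CellShape(phi=phi_new, grid=shape.grid, x_cor=x_cor_new,
                     reference_area=shape.reference_area,
                     steps_since_reinit=count)


def run_morphology(shape: CellShape, activity_fn: Callable[[float, np.ndarray], np.ndarray],
                   p: MechParams, dt: float, n_steps: int,
                   record_every: int = 10) -> List[dict]:
    """Drive a shape with time/position-dependent activity.

    ``activity_fn(t, nodes)`` returns wave activity per boundary node
    (nodes in grid-index coordinates).  Returns snapshots with boundary
    polygons, areas, and times.
    """
    p.validate()
    out: List[dict] = []
    t = 0.0
    for i in range(n_steps):
        nodes = boundary_nodes(shape.phi)
        if len(shape.x_cor) != len(nodes):   # defensive resync
            shape.x_cor = np.resize(shape.x_cor, len(nodes))
        act = activity_fn(t, nodes)
        sigma = total_stress(shape, act, p)
        v_mem, x_cor = viscoelastic_step(shape.x_cor, sigma, p, dt)
        # respect the CFL bound by sub-stepping if needed
        vmax = float(np.max(np.abs(v_mem))) if len(v_mem) else 0.0
        n_sub = max(1, int(np.ceil(vmax * dt / (0.45 * shape.grid.spacing))))
        shape.x_cor = x_cor
        for _ in range(n_sub):
            shape = evolve(shape, v_mem, dt / n_sub)
            if n_sub > 1:
                nodes_new = boundary_nodes(shape.phi)
                v_mem = np.resize(v_mem, len(nodes_new))
        if i % record_every == 0 or i == n_steps - 1:
            out.append({"t": t, "area": shape_area(shape),
                        "nodes": boundary_nodes(shape.phi).copy(),
                        "shape": shape})
        t += dt
    return out
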