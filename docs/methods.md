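# Methods

## Model

Two activator–inhibitor excitable networks share one functional form: an
activator `F` with linear decay `a1`, inhibitor-dependent decay `a2·R_eff`,
an autocatalytic Hill term `a3·F²/(a4²+F²)`, and basal production `a5`; and
an inhibitor `R` that relaxes toward `c1·F` at rate `eps`.  Both fields
diffuse.  The slow network (STEN) organizes propagating waves; the fast
network (CEN, `eps_c = 8·eps_s`) cannot sustain waves of its own — its
excursions are brief and spatially confined, which is what renders the
trailing actin band punctate.  STEN drives CEN through
`s_in = s_c·(R_S − r0)`, which offsets CEN's effective inhibition
(equivalently, raises its activator nullcline), so CEN fires
deterministically under a passing wave and stochastically at the elevated
basal level behind it.  CEN feeds back on STEN only through the noise
amplitude `σ_N = u_b + Z_C − W_C` (clamped at zero): `Z_C` is fast and
local (it travels with CEN activity and promotes STEN triggering nearby),
`W_C` slow and near-global (its steady-state gain is twice `Z_C`'s, so
sustained CEN activation ultimately silences STEN triggering).  The clamp
is a modeling choice: a standard deviation cannot be negative, and the
clamped regime is exactly the "strong global inhibition" state produced by
constitutive CEN activation.

### Default parameters

All quantities are nondimensional (one time unit ≈ the activator lifetime
`1/a1s`; one space unit = one grid step).  The defaults were fixed by a
calibration procedure, not copied from any published table:

| group | values | why |
|---|---|---|
| STEN reaction | `a1s=1, a2s=2, a3s=10, a4s=1, a5s=0.1, c1s=10` | cubic nullcline with a fold (bistable window `R ∈ [0.495, 2.051]`), a single stable rest state on the left branch (`F*=0.0617, R*=0.617`), threshold `th=0.122`, stopping level `R_stop=1.866` comfortably inside the window |
| STEN rates | `eps_s=0.03` | slow inhibitor; the singular-perturbation speed/stopping analysis is quantitative at this delay, and deterministic 1D pulses propagate robustly (they fail for `eps_s ≳ 0.06` in this nullcline family because the inhibitor overshoot truncates the excursion) |
| STEN diffusion | `d_fs=1, d_rs=3` | inhibitor out-disperses activator (`sqrt(3/0.03) ≈ 10 ≫ sqrt(1/1) = 1`), giving finite wave range (~130 grid steps) without quenching the launch |
| STEN noise | `u_b=0.3` | smallest basal drive for which 2D fields (64²–200²) keep nucleating waves indefinitely after equilibration; at 0.25 the field goes quiescent, at ≥0.4 self-raised ambient inhibition suppresses nucleation |
| CEN | same reaction constants as STEN, `eps_c=0.24`, `d_fc=0.3, d_rc=0.5`, `s_c=1` | identical nullclines (the two networks differ mainly in time scale); smaller diffusion keeps firings local |
| CEN noise | `sigma_c=0.55` | calibrated so that, uncoupled, ≥90% of grid sites fire at least once per 100 time units (measured: 91%) |
| feedback | `p1=0.5, p2=0.1, p3=0.05, p4=0.02`, `d_zc=0.3, d_wc=500` | `Z` lifetime 2 (fast/local), `W` lifetime 20 (slow); steady-state gain ratio `(p4/p3)/(p2/p1) = 2`; `d_wc` large enough that `W_C`'s spatial variation stays below 1% on the grids used |

`r0` in the config equals the STEN resting inhibition for the default
reaction constants; it is stored explicitly because the coupling and the
threshold are defined relative to it.

## Numerics

Explicit Euler–Maruyama with the central-difference Laplacian (3/5-point
stencil).  No-flux boundaries use zero-gradient ghost nodes (half-sample
reflection), which conserves mass discretely and is the stencil that the
DCT-II diagonalizes; periodic boundaries are available.  The time step is
enforced at `dt ≤ h²/(4·D_max)` over the explicitly diffused fields and
defaults to 40% of that bound.  `W_C`'s diffusivity (500) sits far above
the explicit bound, so its diffusion substep is applied exactly in the
eigenbasis of the same stencil (DCT/FFT with multiplier `exp(D λ dt)`) —
unconditionally stable, and it leaves the time step set by the ordinary
fields.  Fields are floored at zero after each step (concentrations);
simulations start from the deterministic resting equilibrium with a
burn-in before measurement.  Runs are bit-reproducible from (config, seed).

Noise enters as independent per-site Gaussian increments,
`σ_N·sqrt(dt)` on `F_S` and `sigma_c·sqrt(dt)` on `F_C`.

The level-set module represents the boundary as the zero set of a signed
distance field.  Stress composition (the named effects are modeled as:
linear activity drive, curvature·tension, and a proportional volume
penalty) is evaluated at contour nodes; curvature is `div(∇φ/|∇φ|)`
sampled at nodes.  The cortex displacement uses the exact exponential
update of its linear relaxation (stable at any `dt`; exact when the stress
is held constant over a step); the membrane velocity is extended to the
grid by nearest boundary node and advected with a Godunov upwind scheme
under a CFL guard (`max|v|·dt ≤ 0.5h`).  φ is re-distanced every 10 steps
from its sign pattern (Euclidean distance transform with half-pixel
offset), which keeps `|∇φ|` within 5% of 1 near the interface.

## Wave theory conventions

* Threshold: `th = r0 − R_min` with `R_min` the fold minimum of the cubic
  activator nullcline.
* Net area: adaptive quadrature (absolute tolerance 1e-10) of the
  activator rate between its outer roots; roots from a bracketing scan at
  1e-4 resolution polished to 1e-9.
* `R_stop`: bisection of the net area to 1e-9.
* Measured front position: half-maximum crossing of the activator field,
  linearly interpolated; speed by linear regression over the middle 60% of
  the transit (robust to launch and stall transients).
* Range: distance from the trigger to the last site whose activator peak
  reached 10% of the global pulse peak.
* Speed–threshold scans clamp the inhibitor field at `R0` (the singular
  limit in which speed ∝ net area is exact); the free-running stall level
  is instead measured on a decelerating pulse by extrapolating the
  speed-versus-front-inhibition relation to zero speed.  Only signs,
  zeros, and monotone order of the speed–area relation are asserted; the
  proportionality constant is never computed.
* Molecular dispersion `sqrt(D·τ)` uses lifetimes `1/a1s` (activator) and
  `1/eps_s` (inhibitor) — the leading-order decay rates.

## Quantification pipeline

Biosensor peak distance: both profiles are smoothed with a 19-pixel
centered moving average (edges shrink symmetrically), and the signed
argmax offset is scaled by the pixel size; ties break toward the first
index, and a flat profile triggers a warning.  Wave fronts are segmented
at mean + 1·sd with objects under 9 px removed (8-connectivity); an
optional Gaussian pre-smoothing is exposed for noisy frames.  Speed is the
mean frame-to-frame nearest-edge displacement of front-boundary pixels,
gated to [0.1, 5] length units by default (the gate rejects matches across
different fronts; the units are configurable because microscopy and
simulation length scales differ).  The fraction of fastest pixels is the
fraction of accepted displacements at least one standard deviation above
the video-wide mean.  Puncta are segmented objects of 4–100 px linked
across frames by nearest centroid within 2 px; lifetimes are
`(last − first + 1)·frame_interval`, with tracks touching the movie's
first or last frame dropped as censored.

## Synthetic data

The generator emulates the geometry of two-channel basal-surface movies:
a diffuse single-Gaussian STEN band and a CEN band with a bright leading
peak, a dimmer trailing peak, and an intermediate-intensity floor between
them, translating at a programmed speed; trailing puncta appear as a
spatio-temporal Poisson process with exponential lifetimes (only the mean
was available to match, so exponential is the maximum-entropy choice) and
stay where born.  Defaults (0.25 µm pixels, 5 s frames, 0.2 µm/s waves,
10.8 s puncta, band widths of a few µm) are plausible confocal scales for
giant-cell cortical waves; no numeric pixel size or frame rate was
available to copy, so these are recorded in the movie metadata and carried
through every estimate.  Noise is additive Gaussian by default with
optional Poisson shot noise.  What passing recovery tests show is that the
estimators are unbiased at these contrasts and densities; they do not show
robustness to real-microscopy nuisances (bleaching, uneven illumination,
cell-boundary occlusion), which the generator deliberately omits.

## Study protocols and problem sizes

The reference protocols (`stencen.studies`) run at desk scale: stochastic
2D runs on 64×64 grids for 300 time units after a 150-time-unit
equilibration (the slow inhibitor needs several multiples of `1/eps_s`
before before/after comparisons are meaningful — the 20-unit burn-in that
suffices for plain simulations is not stationary), 1D theory runs on
800–3000-point grids.  Acute recruitments are 10-time-unit linear ramps.
Preset magnitudes are frozen: PIP2 depletion raises `a3s` 10→11.5
(Ras activation, modest: →10.5); PKB recruitment raises `c1s` 10→13 and
`a3c` 10→12; constitutive Rac activation drives CEN to a stable high state
(`a3c`→16, `a1c`→0.6, `c1c`→2); actin depolymerization silences CEN
(`sigma_c=0, a5c=0, s_c=0`).

One measurement subtlety is documented rather than hidden: in the
self-organized stochastic steady state, the ambient inhibition adapts to
parameter changes, and the edge-displacement estimator conflates front
motion with the turnover of short-lived firings.  Threshold-lowering
presets still show their speed increase in the stochastic before/after
comparison, but threshold-raising (PKB) converts waves into sub-frame-
lifetime flashes whose apparent edge displacement is turnover, not motion.
The PKB speed direction is therefore assessed on matched deterministic
triggered waves at the pre/post parameter sets (where it is unambiguous
and large: propagation fails outright at `c1s=13`), while its patch
fragmentation (count up, area down) is measured on the stochastic run.

## Known limitations

* The nullcline family constrains the inhibitor-nullcline slope from
  below (monostability), which couples excursion amplitude to inhibitor
  overshoot; robust deterministic propagation needs `eps_s ≲ 0.05`.
* The net-area speed relation is used qualitatively (order/sign), as the
  eikonal prefactor and curvature corrections are out of scope.
* Level-set re-distancing is EDT-based (first-order near the interface);
  adequate for the area/protrusion properties asserted, not for
  high-curvature shape fidelity.
* The stochastic steady state is self-organized; quantitative speed
  comparisons across parameter sets are only meaningful through the
  matched triggered-wave protocol above.
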