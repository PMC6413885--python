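# stencen

Coupled excitable-network simulation and analysis of cortical waves.

Migrating cells such as *Dictyostelium* organize their protrusions through
propagating waves on the basal cortex.  Two coupled excitable networks
drive these waves: a **s**ignal-**t**ransduction **e**xcitable **n**etwork
(STEN — Ras/Rap, PIP3, PKB) that initiates and propagates the wave, and a
faster **c**ytoskeletal **e**xcitable **n**etwork (CEN — Rac, F-actin,
coronin) that is slaved to STEN and produces the sharp two-peak actin bands
and short-lived puncta seen in biosensor movies.  `stencen` implements this
coupled model, the phase-plane theory of wave speed and stopping, a
level-set viscoelastic simulation of the resulting cell shapes, and the
image-quantification pipeline used to measure waves — plus a synthetic-
movie generator so that every estimator can be tested against known ground
truth.

The package is aimed at quantitative cell biologists and modelers who want
to simulate excitable cortical dynamics, reason about what sets wave speed
and range, or benchmark wave-quantification code.

## The model

Each network is an activator–inhibitor pair on a 1D/2D grid.  STEN:

```
∂F_S/∂t = D_Fs ∇²F_S − (a1s + a2s R_S) F_S + a3s F_S²/(a4s² + F_S²) + a5s + U_N
∂R_S/∂t = D_Rs ∇²R_S + ε_S (−R_S + c1s F_S)
```

CEN has the same form, roughly eight-fold faster (ε_C = 8 ε_S), with the
STEN output entering through the coupling `s_in = s_c (R_S − R_0)`, which
offsets CEN's effective inhibition (`a2c (R_C − s_in)`) and so lowers its
firing threshold as a wave passes.  CEN feeds back onto STEN's stochastic
drive `U_N` (zero-mean Gaussian, standard deviation `σ_N = U_b + Z_C − W_C`,
clamped at zero) through a fast local positive species `Z_C` and a slow,
effectively global negative species `W_C`:

```
∂Z_C/∂t = D_Zc ∇²Z_C − p1 Z_C + p2 F_C
∂W_C/∂t = D_Wc ∇²W_C − p3 W_C + p4 F_C
```

Phase-plane theory connects the cubic activator nullcline to wave behavior:
the firing threshold is `th = R_0 − R_min` (resting inhibition minus the
nullcline's fold minimum), front speed tracks the net signed area under the
activator rate between its outer roots, and waves stop where that area
vanishes (`R_stop`).  Cell morphology follows by converting CEN activity at
the boundary into normal stress on a viscoelastic membrane/cortex pair,

```
ẋ_mem = −(K/D) x_cor + (1/D + 1/B) σ_tot
ẋ_cor = −(K/D) x_cor + (1/D) σ_tot
```

whose membrane velocity advects a signed-distance level set.

See `docs/methods.md` for assumptions, parameter choices, and limitations.

## Worked example

Trigger a deterministic 1D wave, measure its front, and compare the stall
level against the analytic stopping prediction:

```python
import numpy as np
from stencen import ModelParams, wave_theory as wt
from stencen.simulate import front_trace_1d

p = ModelParams().sten                 # excitable defaults, eps_s = 0.03
print(round(wt.threshold_level(p), 4)) # 0.1225  firing threshold
print(round(wt.r_stop(p), 4))          # 1.8655  analytic stopping level

tr = front_trace_1d(p, n=1500, duration=400.0)
speed = wt.measure_front_speed(tr["positions"], tr["times"])
print(round(speed, 2), round(tr["range"]))   # 1.19 129
```

The wave travels at about 1.2 grid steps per time unit and stalls after
~129 grid steps: the slowly accumulating inhibitor diffuses ahead of the
front and shuts propagation down as the pre-front inhibition approaches
`R_stop`.  A full stochastic 2D run with the acute PIP2-depletion preset:

```python
from stencen import studies
res = studies.before_after_study("inp54p", seed=7)
pre, post = res["R_S"]
print(round(pre.mean_speed, 2), round(post.mean_speed, 2))  # 0.85 1.09
```

Raising STEN's autocatalytic feedback lowers the threshold, and the
measured wave speed increases after the recruitment ramp.

A command-line interface mirrors the library:

```
stencen simulate --preset inp54p --seed 1 --grid 100x100 --out out/
stencen theory --scan r0=0.7:1.9:8 --out theory/
stencen analyze --movie out/sten.tif --pixel-size 1 --frame-interval 2 --out report/
stencen synth --fixture fig2-movie --seed 1 --out synth/
stencen morph --traj out/ --out shapes/
```

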