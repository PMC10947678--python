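# epimap

Bifurcation maps, bursting paths and seizure dynamotypes for the Epileptor
and a degenerate Takens–Bogdanov (DTB) bursting model.

## The scientific problem

The Epileptor is a six-variable phenomenological model of focal seizure
dynamics used at the node level of personalized whole-brain epilepsy models.
Transitions between the interictal (resting) and ictal (seizing) states are
bifurcations of its fast subsystem, and a seizure class — a *dynamotype* —
is the pair of bifurcations at seizure onset and offset (e.g. SN/SH:
saddle-node onset, saddle-homoclinic offset, the square-wave burster).
This package is for modellers who want to

* compute, in closed form, the bifurcation geometry of the Epileptor's fast
  subsystem with **all eight coefficients explicit**,
* build the simulation-based amplitude/frequency **map** over the two
  slowly-driven parameters and infer the saddle-homoclinic curve from the
  frequency scaling,
* project full-model trajectories onto that map as **paths** and classify
  the resulting burster's dynamotype automatically, and
* compare the Epileptor map side by side with the generic DTB layer model
  that predicts which dynamotypes are reachable.

## The model

The full Epileptor (state order `x1, y1, z, x2, y2, u`):

```
ẋ₁ = y₁ − x₁³ + 3x₁² − z + I_rest1                     (x₁ < 0)
ẋ₁ = y₁ + m̄ x₁ − z + I_rest1,  m̄ = 0.6α(z−4)² + m − x₂  (x₁ ≥ 0)
ẏ₁ = y₀ − 5x₁² − y₁
ż  = (4(x₁ − x₀) − z)/τ₀
ẋ₂ = −y₂ + x₂ − x₂³ + I_rest2 + u − 0.3(z − 3.5)
ẏ₂ = −y₂/τ₂                         (x₂ < −0.25)
ẏ₂ = (−y₂ + 6(x₂ + 0.25))/τ₂        (x₂ ≥ −0.25)
u̇  = 0.002 x₁ − γ u
```

with defaults `x₀ = −1.6, y₀ = 1, τ₀ = 2857, τ₂ = 10, τ₁ = 1,
I_rest1 = 3.1, I_rest2 = 0.45, γ = 0.01, m = 0, α = 1`.  `u` is the low-pass
filtered drive from the fast to the intermediate subsystem, implemented as a
seventh state equation (exact for the exponential kernel).  The simulated
field potential is `x₂ − x₁`.

The isolated fast subsystem, with every coefficient explicit, is

```
ẋ = νy + ax³ + bx² + μ   (x < 0)        ẋ = νy + m̄x + μ   (x ≥ 0)
ẏ = y₀ + Bx² + Ny
```

(defaults `ν = 1, a = −1, b = 3, B = −5, N = −1, y₀ = 1`).  The slow
variables drag `(μ, m̄)` along the path `μ = I_rest1 − z`,
`m̄ = 0.6α(z−4)² + m − x₂`.  In the `(μ, m̄)` plane the package derives in
closed form the fold curves SN⁻ and SN⁺, the pseudo-fold SN⁰ at the
piecewise seam, the Hopf line `m̄ = −N`, and the Takens–Bogdanov point where
Hopf and SN⁺ meet; the saddle-homoclinic curve is inferred from simulation.
A three-variable DTB layer model (`ẋ = −y`,
`ẏ = x³ − μ₂x − μ₁(z) − y(ν(z)+x+x²)`, `ż = c(x − x₀)` with affine
`μ₁(z), ν(z)`) provides the generic map the Epileptor is compared with.

## Worked example

```python
from epimap import FastParams, sn_curves, hopf_curve, tb_point, run_preset
from epimap.bifurcations import bifurcation_set
from epimap.paths import classify_burster, detect_transitions
from epimap.presets import get_preset

fp = FastParams()
sn, h, tb = sn_curves(fp), hopf_curve(fp), tb_point(fp)
print(sn.sn_minus, sn.sn_zero, h.mbar, (tb.mu, tb.mbar, tb.x))

traj, report = run_preset("sn_sh")           # square-wave preset, Irest2 = 0
params = get_preset("sn_sh").make_params()
events = detect_transitions(traj, params=params)
result = classify_burster(traj, bifurcation_set(fp), events, params)
print(result.label, result.diagnostics["onset"], result.diagnostics["offset"])
```

prints (abridged):

```
SN-  : mu = 0.185185            # = 5/27, rest branch fold
SN0  : mu = -1.000000           # branch merge at the seam (mbar <= 0)
Hopf : mbar = 1.000000          # valid for mu > -1.05
TB   : (mu, mbar, x) = (-1.05, 1.0, 0.1)

preset sn_sh -> SN/SH
  onset  at t = 5345.8, (mu, mbar) = (+0.185, +1.739)
  offset at t = 6064.1, (mu, mbar) = (-0.951, +1.125)
  inter-peak interval at offset / median = 2.52
```

The detected onset sits on the SN⁻ fold (`μ = 5/27 ≈ 0.185`): the resting
branch vanishes there and the orbit jumps to the fast limit cycle with a DC
shift.  The offset lies left of the oscillatory region with the inter-peak
interval stretched to 2.5× its median — the frequency scaling to zero that
marks a saddle-homoclinic offset.  Other presets (`original`, `depol_block`,
`suph_sh`, `suph_suph`, `dtb_sn_sh`) reproduce the classes SN/SupH, SN/SN,
SupH/SH and SupH/SupH, and the DTB square-wave burster; `epimap presets
list` enumerates them.

A command line mirrors the library:

```
epimap curves --defaults --out out/          # analytic SN/Hopf/TB set as CSV
epimap map --model fast --grid 21x21 --out out/map
epimap classify --preset sn_sh --out out/    # prints "SN/SH"
epimap sweep-x0 --preset sn_sh --x0-values -2.0 -1.9 -1.8 --out out/
```

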