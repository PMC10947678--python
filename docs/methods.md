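# Methods

## Models and state conventions

Three deterministic, noise-free ODE systems are implemented (`epimap.models`):
the full six-variable Epileptor, its isolated two-variable fast subsystem
with all eight coefficients (`ν, a, b, μ, m̄, y₀, B, N`) explicit, and a
three-variable bursting model on the `μ₂ = 0.07` layer of the degenerate
Takens–Bogdanov unfolding.  The Epileptor state order is fixed as
`(x1, y1, z, x2, y2, u)` in memory and in every CSV.

Two modelling choices are baked into the right-hand sides:

* **Filter state.**  The low-pass filtered drive
  `u(t) = 0.002 ∫ e^{−γ(t−τ)} x₁(τ) dτ` is implemented as the ODE
  `u̇ = 0.002·x₁ − γ·u` with `u(t₀) = 0`.  This is exact for the exponential
  kernel and avoids storing history; the test suite checks the identity
  against direct quadrature (relative error ≤ 1e−6) and against the closed
  form for constant input.
* **Piecewise branches.**  The `x₁` equation switches branch at `x₁ = 0`
  and the `y₂` equation at `x₂ = −0.25`.  Both branch pairs are continuous
  at their seam (verified by property tests), so branch selection happens
  inside the RHS and the integrator steps straight through; no event
  detection is used.  The generalised `x₁ ≥ 0` branch uses
  `m̄ = 0.6α(z−4)² + m − x₂`, so the classic equations (`α = 1`) and the
  flipped-slope variant (`α = −1`) are one code path.

## Analytic bifurcation geometry (`epimap.bifurcations`)

Fixed points lie on `y = −(y₀ + Bx²)/N`, with `x` a root of a cubic
(`x < 0`) or a quadratic (`x ≥ 0`).  The cubic is solved with the
closed-form trigonometric/Cardano method (imaginary-part tolerance 1e−10)
rather than an iterative solver, so behaviour at double roots (folds) is
deterministic.  Stability comes from the trace and determinant of the
one-sided Jacobian; the seam point `x = 0` is labelled non-hyperbolic
because the Jacobian limits disagree there, and for the same reason the
branch-merge locus `SN⁰: μ = νy₀/N` (for `m̄ ≤ 0`) is exported as a
*pseudo*-fold with its own label — dynamically it acts as a saddle-node for
bursting, but it is not one.

Closed forms, each cross-checked in tests against a brute-force oracle
(discriminant sign change / bisection on root counts / trace sign scan):

* `SN⁻: μ = νy₀/N − (4/27a²)(b − νB/N)³` (= 5/27 at defaults),
* `SN⁺: μ = νy₀/N − Nm̄²/(4Bν)`,
* `SN⁰: μ = νy₀/N` (= −1), `m̄ ≤ 0`,
* Hopf: `m̄ = −N` (= 1) on the upper branch, valid where `det J > 0`, i.e.
  `μ > SN⁺(−N)`; the `x < 0` trace-zero candidates fail the fixed-point
  condition, so no negative-branch Hopf exists,
* TB point: `(μ, m̄, x) = (SN⁺(−N), −N, m̄N/2νB)` (= (−1.05, 1, 0.1)),
  where trace and determinant vanish simultaneously.

A note on orientation: the upper (`x ≥ 0`) fixed point has
`trace J = m̄ + N`, so with `N = −1` it is **stable below** the Hopf line
(`m̄ < 1`, the "active rest") and unstable above it, and the stable limit
cycle lives **above** the line.  All map and path logic follows this
orientation, which direct simulation confirms.

Points within 1e−8 of an analytic curve are tagged "on-curve" rather than
assigned to a region, since root multiplicity there is numerically
ambiguous.

## The map protocol (`epimap.mapgrid`)

Because the saddle-homoclinic (SH) curve is a global bifurcation of a
piecewise system, it is located by simulation.  Per grid cell the fast
subsystem starts at the non-resting fixed point (largest-`x` root for the
Epileptor, whose rest is the lower branch; smallest-`x` root for the DTB
layer, whose rest is the upper branch) offset by `(ε, 0)`; the protocol is
600 time units with the first 300 discarded and `ε = 0.05` for the
Epileptor, and 2000/500 with `ε = 0.0005` for the DTB layer, whose
attraction rates are two orders of magnitude smaller.  Amplitude is
max − min of `x` over the retained window; frequency is the dominant peak of
the Hann-windowed DFT (zero bin excluded) refined by quadratic interpolation
of the three bins around the maximum, reported in Hz with model time read as
seconds and resolvable in multiples of `1/(t_total − t_discard)`.  A cell
"converged to a fixed point" when the amplitude of the trailing fifth of the
window falls below 1e−3 `x`-units (two orders below typical cycle
amplitudes).  Output samples are taken at `dt = 0.1`.

The sweep integrates **all cells simultaneously** with a fixed-step
classical Runge–Kutta scheme at step 0.02 — five times finer than the 0.1
step cap used everywhere else; the isolated fast subsystems are small and
non-stiff, a 17×20 map takes a few seconds, and identical protocols give
bit-identical matrices.  Cells whose integration overflows are flagged
`diverged`, not fatal.

Region classification combines the analytic fixed-point census with the
simulated limit-cycle flag.  On the standard rectangle
`μ ∈ [−2, 1] × m̄ ∈ [−3, 2]` (grid chosen so no node lands exactly on an
analytic curve) exactly five configurations
`(n_stable_fp, n_fp, has_lc)` appear: `(1,1,False)` single rest state,
`(2,3,False)` bistable fixed points, `(1,3,True)` rest + cycle,
`(1,3,False)` three fixed points with only rest attracting, and
`(0,1,True)` — the cycle as only attractor.  `classify_region` additionally
integrates from a second start (beside the resting point) before declaring
a cell cycle-free.

**SH inference.**  For each `m̄` row the oscillatory run's edge that abuts a
three-fixed-point cell (a saddle must exist for the homoclinic) is the SH
candidate; the boundary `μ` interpolates the measured frequency down to a
floor of twice the DFT bin width.  The inference rests on the decaying
frequency trend, not the exact cutoff; the boundary is therefore located to
about half a grid cell.  The resulting polyline starts within one grid cell
of the TB point and climbs toward the SN⁻ fold, and refining the grid 2×
moves each vertex by less than one coarse cell.

**Hopf criticality caveat.**  Just above the Hopf line the attractor
amplitude is small (~0.4) only near the TB corner; at `μ ≈ 0` the amplitude
onset is explosive (≈ 0.95 already at `m̄ = 1.0005`).  The amplitude still
collapses to zero *across* the line everywhere, which is what the map tests
assert; full-model "SupH offset" amplitude decay is the slow passage of the
orbit below the line.

## Integration engine (`epimap.simulate`)

Full-model trajectories use `scipy.integrate.solve_ivp` with LSODA,
`max_step = 0.1`, `rtol = 1e−8`, `atol = 1e−10`, and fixed output sampling
at `dt = 0.1` (≥ 20 samples per fast oscillation).  Presets start from the
resting branch at `z = 3` — `x₁` the most negative cubic root at
`μ = I_rest1 − 3`, `y₁` on its nullcline, intermediate and filter states at
zero — a convention chosen to remove dependence on arbitrary starts;
downstream analyses treat the first burst as transient and classify the
last complete one.  Preset spans (8000–12000 time units, ≥ 3 bursts) were
chosen to keep a full run in single-digit seconds.  Presets use `x₀ = −2`
(the scenario-illustration value); the library default stays `−1.6`.

## Event detection and dynamotype classification (`epimap.paths`)

The projection onto the map is algebraic and unsmoothed:
`μ = I_rest1 − z`, `m̄ = 0.6α(z−4)² + m − x₂` with the raw `x₂`.

Onsets/offsets of fast oscillation are found on the *detrended* `x₁`
(sliding mean over one envelope window removed — the DC jumps of fold
transitions would otherwise register as amplitude) with a sliding
max − min envelope, window 50 time units (≫ fast period ≈ 4–6, ≪ burst
length), hysteresis thresholds `amp_on = 0.5 > amp_off = 0.2`.  Two
refinements matter:

* episodes shorter than two windows are discarded as jump transients;
* an onset is re-anchored to the first exceedance that *persists* for 1.5
  windows: a fold's ring-down keeps the envelope high for about one window,
  so without this a fold transition followed by driven sub-threshold
  wiggles would be glued to a later oscillation onset (this is what
  separates SN from SupH onsets when the intermediate subsystem is active),
  and is then pinned to the first raw threshold crossing to undo the
  centred envelope's half-window lead.

When no oscillation episode exists, events are branch alternations of the
smoothed `x₁` through the inter-branch level −0.7 (the unstable middle
branch lies in (−4/3, 0) for all default-coefficient maps), giving the
SN/SN (depolarization-block) class.

Classification of the last complete episode: the onset type is the nearest
analytic curve at the onset path point (`|μ − SN⁻|` vs `|m̄ − Hopf|`; both
coordinates are O(1) so raw distances are comparable), with the amplitude
at onset kept as a diagnostic.  The offset type combines the side of the
Hopf line at the offset point (above → SH, below → SupH) with the
inter-peak-interval trend (last ISI > 1.8× median → SH); disagreement
yields "ambiguous" with both votes reported.  A DC-shift diagnostic
(baseline change > 0.5) accompanies SN-bounded classes.  All five preset
labels are invariant under halving the solver tolerances and halving the
envelope window.

Detection accuracy: SN onsets land within 0.5% of `μ = 5/27`.  SupH onsets
are detected at `m̄ ≈ 1.15–1.25` rather than exactly 1 — deterministic slow
passage through a Hopf delays the visible oscillation, an effect of the
dynamics, not the detector — so the onset-location test uses a 25% band for
Hopf onsets versus 5% for folds.

## Presets and the α = −1 search

`original` (m = 0, I_rest2 = 0.45) → SN/SupH, `sn_sh` (m = 0,
I_rest2 = 0) → SN/SH, and `depol_block` (m = −8, I_rest2 = 0) → SN/SN use
long-established parameter values.  The two flipped-slope scenarios have no
published `m`; `scripts/find_alpha_presets.py` scans `m` and classifies
each candidate.  With `I_rest2 = 0` the filtered drive falls during an
oscillation, `x₂` falls, and `m̄` drifts upward, so the cycle always exits
through the SH side: SupH/SH appears (frozen at `m = 0.40`) but SupH/SupH
cannot.  With `I_rest2 = 0.45` the intermediate spikes carry `m̄` back
below the Hopf line and SupH/SupH appears for `m ∈ [0.05, 0.20]` (frozen at
`m = 0.10`).  The DTB preset's path constants
(`μ₁ = −0.01·z`, `ν = 0.02`, `c = 0.001`, `x₀ = 0.1`) are constructed, not
published: `x₀` must lie between the cycle's mean `x` and the resting `x`
for the slow variable to reverse, and the path must straddle the layer's
folds at `μ₁ = ±0.00714`.

## Role of the epileptogenicity x₀

For the pure hysteresis loop (`I_rest2 = 0`) `x₀` sets the speed of the
slow variable, not the route: interictal duration shortens monotonically as
`x₀` rises (1703 → 1153 time units across −2.0 → −1.8), and projected cycle
paths coincide to about 1.4% of the cycle's arc length (symmetric Hausdorff
metric, `paths.path_overlap`).  The residual is a real second-order effect:
the fold-crossing overshoot and the filter lag both scale with the
slow-variable speed, which is exactly what `x₀` controls, so path
invariance is approximate rather than exact.  Bursting requires
`x₀ ≳ −2.06` at these settings; below that the z-nullcline crosses the
resting branch and the whole system sits in a fixed point, which the sweep
flags as `no_bursting`.  With `I_rest2 = 0.45` the per-burst count of
intermediate spikes changes with `x₀` (12/13/14 across −2.0/−1.9/−1.8).

## What the tests do and do not show

All inputs are parameter sets; there is no external data and no noise.
Deterministic simulations at the stated protocol sizes are the evidence:
tests verify curve values, region counts, frequency scaling, class labels
and invariances, not pixel-level renderings.
Grid resolutions (17×20 standard map) and preset spans were chosen as the
smallest sizes at which the qualitative structure (five regions, SH trend)
is stable under refinement.  Conclusions about real seizure recordings —
noise-driven onsets, networks of coupled units, chaotic transitions — are
out of scope: the package characterises the deterministic skeleton that
those studies build on.

## Known limitations

* No numerical continuation: the SH curve is a half-cell-accurate polyline,
  not a continued branch; no codimension-2 analysis beyond the TB point.
* Offset classification near the SH/SupH decision boundary can return
  "ambiguous" (by design) when the ISI trend and the map-side vote
  disagree.
* The region census trusts the two-start limit-cycle probe; a cycle whose
  basin excludes both starts would be missed (none exists on the mapped
  rectangle, by the map sweep's own evidence).
* Frequencies assume model time is seconds; rescale if another unit is
  intended.
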