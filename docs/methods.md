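# Methods

## Scope and assumptions

The package models the protofibril-elongation stage of Aβ42 aggregation as
deterministic mass-action kinetics in a well-mixed, homogeneous solution.
Spatial effects, molecular crowding and stochastic fluctuations are outside
scope, as is estimating the nucleation mass or pre-nucleation constants
from data. Two deliberate simplifications, both bounded approximations of
the full combinatorial problem, define the elongation-stage networks:

* growth by **monomer addition only** — dimer/trimer addition to
  protofibrils is neglected, which is accurate in the first minutes of a
  seeding experiment when free monomer vastly outnumbers oligomers;
* lateral association restricted to **standard-size protofibrils reacting
  with elongated ones** (complete model) or to a **10-fold size cap**
  (stand-alone lateral model). The fully general association of arbitrary
  size pairs grows combinatorially and is intentionally not represented.

All concentrations are millimolar and all times hours internally, matching
the units of the rate constants (h⁻¹·mM⁻¹ for second order, h⁻¹ for first
order). Micromolar values from the experimental convention are converted
exactly once, at the configuration/CLI boundary.

## Species accounting and mass conservation

Every species carries a monomer-equivalent mass (A₁ = 1, F = 1600,
F_i = 1600 + i, G_i = (i+1)·1600, A_i = i) and every reaction balances
exactly: the state vector dotted with the mass vector is a conserved
quantity of the ODE system, which the test suite asserts both at the
right-hand-side level (random states) and along trajectories.

Self-reactions (F + F ⇌ F_1600, G_i + G_i ⇌ G_{2i+1}, A₁ + A₁ ⇌ A₂) use a
forward flux `k·[X]²` and, by default, consume **two** copies of the
reactant per event (`self_reaction_factor = 2`). A single-count option
(factor 1) is provided for comparison with formulations that sum each
reaction's flux once into the reactant derivative, but it breaks mass
conservation for the self-reaction and is therefore not the default.

## Numerical integration

The elongation systems are stiff: 2652 species whose concentrations span
ten or more orders of magnitude, driven by rate constants scanned over
fourteen decades during fitting. The default integrator is SciPy's BDF
with an analytically assembled sparse Jacobian (tridiagonal chain plus
dense rows/columns for the monomer and seed species); Radau and LSODA are
available through `SolverSettings` and agree with BDF to the documented
1e-4 relative tolerance on reference problems. Defaults are
`rel_tol = 1e-6`, `abs_tol = 1e-12` mM. Linear invariants are preserved by
these methods up to solver tolerance, so the observed mass drift is at
round-off level. Solver overshoot can leave a concentration marginally
negative (observed magnitudes below 1e-30 mM); states are reported as
solved and clamped to zero only inside the observable mapping, never in
the state fed back to the solver.

Correctness of the integration path is anchored by independent oracles in
the test suite: a fixed-step classical RK4 reference on ≤5-species chains
(agreement to 1e-6 relative) and the analytic detailed-balance equilibrium
`[F₁]/([A₁][F]) = k_fb,1/k_fb−` of the single-reaction truncation.

## Observable mapping

ThT fluorescence is modeled as `S(t) = b · Σ_i i·[F_i](t)`: each elongated
protofibril contributes in proportion to the number of added monomers (the
newly created binding sites), and the unelongated seed pool F contributes
nothing — its constant offset is removed from data anyway by baseline
subtraction (each series minus its own minimum, applied per series and
idempotent). One consequence of applying the single mapping formula to all
species is that F_i produced by lateral association in the complete model
*do* carry ThT weight. Because those species are heavy (weight ≥ 1600),
the complete model's ThT signal exceeds the simple model's by a few
percent already within the first minute and by more than a factor of two
at an hour. The package treats this overestimation as a feature of the
mapping, not a bug: it reproduces the known failure of ThT to discriminate
lateral association, and it is why the lateral constants are validated
against DLS instead.

DLS count rate uses the same scheme over the lateral model,
`S(t) = b · Σ_{i≥1} w_i·[G_i]` with `w_i = i` by default. Since `b` is a
free scale, any proportional weight family is observationally equivalent
once G_0 is excluded; `w_i = i + 1` (total size) is available as an
option. The mapping constant is one value per modality per fitting run
(defaults 2000 for ThT, 6500 for DLS), never per curve; a per-curve `b`
can be emulated by fitting series individually but is deliberately not a
first-class option.

## Grid search and refinement

Each fitting stage scans one (forward, reverse) pair over the coarse
geometric grid 10⁻⁶…10⁸ × 10⁻⁸…10⁶ at multiples of 10 (15×15 = 225
pairs), scoring every pair by the SSE summed over all curves at once:
one parameter set must explain all seed concentrations with a common `b`.
Selection is on SSE, not R²; R² per curve and its mean are reported as
diagnostics. Ties break toward the smallest forward, then smallest
reverse constant. A failed integration records an infinite SSE for that
point and is skipped.

Because realistic optima sit off the power-of-ten grid, the coarse optimum
is refined on a mantissa ladder {1.0, 1.5, 2.0, 3.0, 4.5, 6.0, 9.0}
spanning the decades one below to one above each constant's current value
(a near-uniform ×1.5 ladder that can represent values such as 9.0×10³,
4.5×10², 6.0×10⁻³). The window is re-centered and re-scanned until the
optimum stops moving (at most six rounds) — necessary because the coarse
scan can park a full decade away from the true optimum. Two exact
optimizations keep the scan cheap without changing its result: evaluated
pairs are cached across stages, and a pair's evaluation is abandoned as
soon as its partial SSE provably exceeds the best SSE seen (SSE only
accumulates over curves).

Simulations are evaluated directly on each dataset's time grid, so no
interpolation enters the fit; a monotone piecewise-cubic (PCHIP) resampler
is provided for grids that do not match.

## Sigmoid fits and lag times

Sigmoidal growth curves are fit to the 4-parameter logistic
`y(t) = y₀ + A / (1 + exp(−(t − t_½)/b))` by least squares (lmfit, TRF
backend), from which lag time `t_½ − 2b` and apparent rate `k_app = 1/b`
follow. The width parameter is written `b_sig` throughout the code to
avoid collision with the observable mapping constant `b_map`. Initial
guesses come from the half-range crossing and the 25–75% crossing
distance; flat series and non-convergent fits raise typed errors.

For the full pathway model the fitted signal is the fibril-mass proxy
`Σ_{i≥n} i·[A_i]`, the natural analogue of the ThT mapping. The default
comparison horizon is 60 h with 600 samples. With the published
insulin-derived constants (k_nu,1 = 1.38, k_nu− = 1.01×10⁻³,
k_fb,1 = 1.37×10⁴, k_fb− = 3.02×10²; n = 6) this signal is strongly
stretched rather than cleanly logistic — most mass stalls in
pre-nucleation oligomers once free monomer is consumed — so the absolute
lag values depend visibly on the fitting window, and at high
concentrations the fitted lag can even go negative. The package therefore
asserts only the robust qualitative content of the comparison: lag times
fall monotonically with concentration and sit far below the measured
Aβ42 lag times (157 h at 10 µM), the discrepancy that motivates
Aβ-specific constants in the first place. The pathway's maximum size is an
explicit, user-set absorbing cap (default 100); the qualitative
conclusions are insensitive to it (checked at 50–300).

## Synthetic data generator

The generator emulates the two assay designs: seeded ThT elongation
(30 µM monomer; 2, 4, 7 µM protofibrils; 1–60 min; 1 s sampling up to
5 min, 30 s at 60 min) and salt-triggered DLS lateral association (4 µM
protofibrils, no monomer, 120 min, 60 s sampling). Clean signals are exact
model trajectories mapped through the observable; corruption is a constant
positive baseline (default 5% of the series range, so baseline subtraction
has real work to do) plus additive zero-mean Gaussian noise (default σ =
2% of range), with a recorded per-series seed. A `TruthRecord` carrying
the generating parameters, model configuration and seeds round-trips
through JSON.

What the generator does **not** emulate — and what recovery tests
therefore cannot demonstrate about real data: instrument artifacts
(photobleaching, dust spikes), signal-dependent or correlated noise,
heteroscedasticity between curves, nonlinearity of ThT response at high
fibril load, and any model misspecification (real elongation includes
oligomer addition; real lateral association is not restricted to
standard-size partners). Passing self-recovery shows the estimator is
consistent under the model's own assumptions, not that the model is true.

Identifiability caveat: over a 2-hour DLS window the dissociation constant
is only visible if its relaxation time is comparable to the window. The
noisy-replicate recovery study therefore uses a generating pair
(k_la = 1.0, k_la− = 1.0) at which both constants shape the curve; at
k_la− ~ 10⁻² h⁻¹ and below, 2% noise can move the recovered reverse
constant by a ladder step while the forward constant stays exact.

## Defaults worth knowing

| Parameter | Default | Units | Why |
| --- | --- | --- | --- |
| k_fb,1 / k_fb− | 9.0×10³ / 4.5×10² | h⁻¹mM⁻¹ / h⁻¹ | elongation best fit |
| k_la / k_la− | 9.0×10⁻¹ / 6.0×10⁻³ | h⁻¹mM⁻¹ / h⁻¹ | lateral best fit |
| b (ThT / DLS) | 2000 / 6500 | signal·mM⁻¹ | per-modality mapping |
| max_elongation | 2650 (derived) | monomers | 64→170 nm saturation |
| lateral_coupling_count | 1051 (derived) | reactions | largest product F_2650 |
| lateral_fold_cap | 10 | — | DLS shows ~5-fold rise in 2 h |
| self_reaction_factor | 2 | — | exact mass conservation |
| size scaling g(i) | i^(−1/3) | — | diffusivity of an i-mer; Smoluchowski kernel optional |
| rel_tol / abs_tol | 1e-6 / 1e-12 mM | — | concentrations span ~10 decades |
| solver | BDF + sparse analytic Jacobian | — | stiff, structured system |

## Known limitations

* The complete model's ThT overestimation at long times is intrinsic to
  the single linear mapping; separating elongation-born from lateral-born
  F_i would require a two-index bookkeeping the networks do not carry.
* Grid-search cost scales linearly in grid points × datasets; the pruning
  and caching keep the full elongation stage to a few minutes, but the
  scan is exhaustive by design — no gradient or Bayesian estimation is
  provided.
* The logistic lag-time definition is fit-window dependent for curves that
  are not genuinely logistic (see the pathway discussion above).
* `reaction_flux`/`rhs` as public functions recompile the model per call;
  the integrator compiles once. For custom tight loops, reuse the
  integrator rather than calling `rhs` repeatedly.
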