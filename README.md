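# abkinetics

Molecular-level kinetic modeling of amyloid-β (Aβ42) protofibril growth.

Soluble Aβ42 protofibrils grow by two distinct mechanisms: **elongation**
(monomers add to protofibril ends, creating new thioflavin-T binding sites)
and **lateral association** (two protofibrils join side-on, invisible to ThT
but visible to dynamic light scattering as a rising count rate). This
package builds the mass-action reaction networks for both mechanisms,
integrates the resulting stiff ODE systems, maps concentrations to ThT and
DLS observables, and estimates the rate constants by grid-search least
squares against multi-concentration seeding data. It is aimed at
biophysicists who want a reproducible, testable version of this style of
top-down aggregation analysis — including a synthetic-data generator that
emulates the seeding experiments so every estimator can be validated by
parameter self-recovery.

## The models

A standard protofibril `F` is idealized as a 1600-mer of ~64 nm. Elongation
saturates at an average length of 170 nm, so at most
`round(1600·170/64 − 1600) = 2650` monomers can add:

* **Simple model** — monomer addition only,
  `A₁ + F_{i−1} ⇌ F_i` (i = 1…2650), with forward constant `k_fb,1`
  (h⁻¹·mM⁻¹) and reverse `k_fb−` (h⁻¹): 2652 species, 2650 reactions.
* **Complete model** — the simple model plus lateral association of
  standard protofibrils with elongated ones,
  `F + F_{m−1} ⇌ F_{m+1599}` (m = 1…1051, constants `k_la`, `k_la−`):
  3701 reactions over the same 2652 species.
* **Lateral model** — a stand-alone, monomer-free network
  `G_i + G_j ⇌ G_{i+j+1}` (i = 0…4, j = i…8−i) over 10 size classes
  `G_0 ≡ F … G_9 ≡ F_14400`, capped at a 10-fold size increase; matched
  against DLS count-rate data.
* **Full pathway model** — the generic nucleation-dependent polymerization
  chain `A_i + A₁ ⇌ A_{i+1}` with slow pre-nucleation (`k_nu,1·g(i)`,
  `k_nu−`) and fast post-nucleation (`k_fb,1·g(i)`, `k_fb−`) regimes,
  `g(i) = i^(−1/3)` by default; used for lag-time comparisons via the
  logistic fit `y = y₀ + A/(1 + e^{−(t−t_½)/b})`, lag = `t_½ − 2b`,
  `k_app = 1/b`.

Observables are linear maps of the state: ThT fluorescence
`S(t) = b·Σ_i i·[F_i]` and DLS count rate `S(t) = b·Σ_{i≥1} i·[G_i]`, with
one mapping constant `b` per modality. Fitting scans each (forward,
reverse) pair over a 15×15 geometric grid (10⁻⁶…10⁸ × 10⁻⁸…10⁶, 225
pairs), minimizing the squared error jointly across all curves, then
refines on a local mantissa ladder; the elongation pair is estimated first
on short curves and held fixed while the lateral pair is estimated
(divide-and-conquer).

## Worked example

Simulate 1 minute of seeded elongation at the package's default best-fit
constants (`k_fb,1 = 9.0×10³ h⁻¹mM⁻¹`, `k_fb− = 4.5×10² h⁻¹`, `b = 2000`)
for 30 µM monomer and three protofibril levels:

```python
import numpy as np
import abkinetics as ak

params = ak.KineticParams()
model = ak.build_simple_model()
t = np.linspace(0, 1 / 60, 61)          # one minute, hours
for pf_uM in (2, 4, 7):
    c0 = model.initial_state(monomer_mM=0.03, protofibril_mM=pf_uM / 1000)
    traj = ak.integrate(model, c0, params, t)
    s = ak.tht_signal(traj, params.b_tht)
    print(f"{pf_uM} uM seed: ThT(60 s) = {s.signal[-1]:.3f} a.u.")
```

```
2 uM seed: ThT(60 s) = 4.071 a.u.
4 uM seed: ThT(60 s) = 7.478 a.u.
7 uM seed: ThT(60 s) = 11.663 a.u.
```

More seed means more growing ends, so the fluorescence after one minute
rises with the protofibril concentration. Generating a noisy synthetic DLS
experiment (120 min, 4 µM protofibrils, 2% noise) and refitting it
recovers the lateral constants:

```python
series, truth = ak.generate_dls_dataset(design=ak.ExperimentDesign.dls_default(seed=7))
fit = ak.grid_search(ak.build_lateral_model(), [ak.baseline_subtract(series)],
                     target_pair="lateral")
print(fit.best_forward, fit.best_reverse, round(fit.r2_mean, 4))
```

```
0.9 0.009000000000000001 0.9965
```

The forward constant comes back exactly (0.9 h⁻¹mM⁻¹); the reverse constant
(truth 6×10⁻³ h⁻¹) lands on the neighboring ladder value because its effect
over a 2-hour window is close to the 2% noise floor — run noise-free to
recover both exactly.

A CLI wraps the same stages: `abkinetics simulate | synth | fit | lagfit`
(see `--help` for each).

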