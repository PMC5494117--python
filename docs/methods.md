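# Methods

## Model structure and assumptions

The package models a bolus-injected radiotracer exchanging between blood
(`z`), tumor cells (`x`) and normal cells (`y`) at first-order rates, with
radioactive decay `λ` and biological elimination `E`:

```
dx/dt = β_zx z − (β_xz + λ) x
dy/dt = β_zy z − (β_yz + λ) y
dz/dt = β_xz x + β_yz y − (β_zx + β_zy + E + λ) z
```

Assumptions baked into this structure:

* **Decay acts on every compartment.** Radioactive decay is
  location-independent, so `λ` appears in all three equations.  This is what
  makes the no-elimination total follow `n₀e^{−λt}` exactly — a property the
  conservation tests check to 1e−9.
* **Elimination acts on blood only.** Renal/biliary elimination removes
  tracer carried by the bloodstream; cellular content leaves only via the
  return rates `β_xz`, `β_yz`.  An alternative reading in which `E` also
  drains the cellular compartments was considered and rejected: it breaks
  the limiting behaviour in which fully retentive cells (`β_xz = 0`) lose
  tracer through decay alone, and it makes the washout ordering between the
  reference scenarios far more extreme than the published curves suggest.
  The choice is documented here because the model's provenance leaves it
  genuinely open.
* **Linearity.** Capture is not saturable; concentrations scale exactly
  with the injected amount `n₀` (the solver computes the unit-dose solution
  and scales it, so dose-linearity holds bit-exactly).
* **Tumor-imaging regime.** The optional `validate_regime()` check asserts
  `β_xz < β_yz` (tumor cells retain more strongly than normal cells) and
  `β_zy < β_zx` (normal-cell uptake is weak) — the conditions under which
  the tracer visualizes tumors.  The fully retentive limit
  `β_xz = β_yz = 0` is accepted as trivially compliant.

## Units and parameters

All rates are h⁻¹ and times are hours (the CLI converts from minutes with
`--minutes`).  Defaults: `n₀ = 1` (concentrations are fractions of the
injected dose); the 6-hour isotope half-life gives `λ = ln2/6 ≈ 0.1155 h⁻¹`.
The named presets fix the remaining rates:

| preset | λ | E | β_zx | β_zy | β_xz | β_yz |
|---|---|---|---|---|---|---|
| fig2_no_elim | 0 | 0 | 1 | 0.5 | 0 | 0 |
| fig3_retentive | 0 | 0.1 | 1 | 0.5 | 0 | 0.5 |
| fig3_leaky | 0 | 0.1 | 1 | 0.5 | 0.1 | 0.5 |
| fig4_decay_no_elim | ln2/6 | 0 | 1 | 0.5 | 0 | 0 |
| fig5_full / fig6a / fig7 | ln2/6 | 0.1 | 0.5 | 0.25 | 0.1 | 0.5 |
| fig6b | ln2/6 | 1 | 0.5 | 0.25 | 0.1 | 0.5 |

The capture ratio `β_zy = β_zx/2` follows the published simulation
convention; experimental reports place the tumor/normal capture ratio
nearer 3–4, and that alternative is accommodated by parameter overrides
rather than a separate preset.  The elimination constant of the `fig3_*`
presets is not printed in the source curves; `E = 0.1` (the weak-elimination
value used throughout the radioactive scenarios) was adopted once and kept.

## Solvers and numerical choices

* **Closed form** — eigendecomposition of the rate matrix; when the
  smallest eigenvalue gap is below 1e−12 (or the eigenvector matrix has
  condition number above 1e12) the solver falls back to a per-time-point
  scaling-and-squaring matrix exponential, which handles defective matrices
  such as the fully decoupled decay-only case.  Roundoff-level negative
  values are clipped to zero; the exact solution is nonnegative.
* **RK4 oracle** — classical fixed-step 4th-order integration, default step
  1e−3 h, subdividing each grid interval so the integrator lands exactly on
  the requested grid.  Closed form and RK4 agree to 1e−6 relative over
  random parameter sweeps (rates in [0, 2] h⁻¹); this is the package's
  primary correctness check, since the two paths share no code beyond the
  rate matrix.
* **K_WOR time points** — the clinical protocol says only "first minutes"
  versus "60–240 minutes".  The default places `t1` at the grid argmax of
  the tumor-minus-normal contrast before `t2` and `t2` at 4 h; both are
  overridable.  For monotonically saturating contrast the argmax lands one
  grid step before `t2` and K_WOR vanishes with grid resolution, which is
  the correct limit for a retention-only system.
* **Threshold boundary** — `K_WOR = 0.45` exactly is classified high-PGP:
  the clinical rule leaves the boundary undefined, and resolving it upward
  makes the high-risk call conservative.
* **Clearance** — trapezoid rule on the grid; optional mono-exponential
  tail extrapolation from the terminal log-slope for the infinite-window
  reading.  The finite-window reading is the default (a diagnostic study
  has a defined end time).
* **Segmentation** — slope thresholding at `rise_frac` (default 0.05) times
  the peak positive slope; the vascular phase is the initial fast-rise run,
  the excretory phase the terminal run of significant decline, the
  secretory plateau everything between.  The three index ranges always
  partition the grid.  For slowly declining tails a smaller `rise_frac`
  (e.g. 0.02) is needed for the excretory phase to register.
* **Background subtraction** — pointwise difference floored at zero (counts
  cannot be negative), with a warning carrying the number of floored points.
* **Fitting** — `Φ = Σ(observed − modelled)²`, minimized by bounded
  nonlinear least squares (trust-region reflective), 8 seeded uniform
  multi-starts within default bounds [0, 10] h⁻¹, gradient tolerance 1e−10,
  at most 500 function evaluations per start.  `λ` and `n₀` are always
  fixed (known isotope, known dose).  Because a single observed compartment
  cannot separate the two capture rates, `β_zy` is tied to `β_zx/2` by
  default whenever `β_zx` is free and `β_zy` is not; freeing all five rates
  against one curve raises an identifiability error unless explicitly
  overridden.  Same seed ⇒ bit-identical result.

## Synthetic data

`generate_noisy_observations` samples the closed-form trajectory of a
preset and adds seeded noise: additive Gaussian (sd in concentration units,
truncated at zero) emulating background-subtracted count rates, or Poisson
counting noise (mean = value × counts-per-unit-concentration, rescaled).
What it deliberately does **not** emulate: detector response and
attenuation, partial-volume effects, patient motion, heteroscedastic
backgrounds, or inter-patient parameter variability.  Passing tests
therefore demonstrate correctness of the computational pipeline under the
model's own assumptions, not clinical performance.

Truncation at zero biases the Gaussian model by less than 1% of the sd
whenever the sd is below ~10% of the smallest trajectory value in the
sampling window; the generator's tests check this regime.

## Identifiability of the elimination constant

A deliberately documented limitation: a blood curve sampled 24 times over
8 h with Gaussian sd 0.005 constrains the weak-elimination scenario's
`E = 0.1 h⁻¹` only up to a sampling standard deviation of ≈0.013
(Cramér–Rao bound computed from the model sensitivities; the package's
estimator attains it empirically, with negligible bias).  Recovering `E`
within 10% relative from such data therefore succeeds in only ~60% of
seeds — a property of the experiment design, not of the optimizer.  The
capture rate `β_zx` is recovered within 10% essentially always, and
tumor-curve observations (whose amplitude responds much more strongly to
`E`) would raise the joint success rate to ~94%.  Studies aiming to
estimate elimination from blood sampling alone need either lower noise,
a stronger elimination rate, or tissue curves.

## Problem sizes

Default analysis grids are 0.01 h over 8–24 h (801–2401 points); the random
oracle sweeps use 100 parameter draws at 16 grid points; recovery studies
use 100 seeds × 24 observations.  These sizes keep every check
comfortably within interactive runtimes while leaving the statistical
conclusions unchanged at larger n.
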