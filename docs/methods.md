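# Methods

## Physical setting and model

A cylindrical elastic tube (internal radius `r`, wall thickness `h`,
rest length `l₀`) is clamped at both ends, axially pre-stretched by a
factor `l`, and loaded by an isotropic external pressure that increases
linearly in time, `p_ext(t) = p_max · t/τ`. With no flow the internal
gauge pressure is zero, so the intramural pressure is `p_intr = −p_ext`.
The geometry is described by three non-dimensional ratios: the
length-to-diameter ratio `d = l₀/D`, the thickness-to-diameter ratio
`γ = h/D`, and the pre-stretch `l` (`D = 2r`). The wall material is
characterized by Young's modulus `E`, Poisson ratio `ν` and density `ρ`;
for large-deformation work the package converts these to Neo-Hookean
coefficients `χ = E/(4(1+ν))`, `λ = νE/((1−2ν)(1+ν))`. The reference
values `E = 1 MPa`, `ν = 0.49`, `ρ = 1000 kg/m³` are representative of
lung conduits.

Buckling into a two-lobed cross-section is a spontaneous symmetry breaking
and is treated as a second-order phase transition. Minimizing the quartic
Landau potential `φ − φ₀ = c₁(ξ − ξ_crit)α² + (c₂/2)α⁴` gives the
mean-field order parameter `α = [−(c₁/c₂)(ξ − ξ_crit)]^{1/2}` below the
transition and 0 above — continuous, with critical exponent 1/2. Taking
the central cross-section area as a representative function of the order
parameter and the loading pressure `p̃ = −p_intr` as the control variable,
the knee of the tube law is fitted with the saturating generalization

    A − A_crit = c₁ tanh( c₂ · s(x)|x|^β ),   x = (p̃_crit − p̃)/p̃,

where `s(x)|x|^β` is the odd (signed-power) extension: the literal power
`x^β` is undefined for `x < 0` (beyond the knee) at fractional `β`, and
the odd extension is the only analytic continuation that continues the
area drop smoothly through the transition. Mean-field theory neglects
fluctuations; the model is phenomenological, which is exactly what is
needed to locate critical points.

## Estimation procedure

1. **Preprocess.** Drop `p_intr = 0` samples (`x` is undefined there),
   flip sign to `p̃`, normalize absolute areas by the first recorded area,
   truncate everything at and beyond the first sample whose normalized
   area falls below the contact threshold (default 0.35 — the wall-contact
   regime is a different physical process, outside the buckling model),
   and sort by `p̃`. At least 8 samples must survive.
2. **Inner fit.** For a fixed candidate `A_crit`, fit `(c₁, c₂, p̃_crit,
   β)` by nonlinear least squares (`scipy.optimize.curve_fit`) with
   bounds `c₁, c₂ > 0`, `β ∈ (0.05, 2)`, and `p̃_crit` inside the observed
   pressure range. Starting values are data-driven: `p̃_crit⁰` at the
   steepest area drop, `β⁰ = 0.5` (mean-field), `c₁⁰ = (max−min area)/2`,
   `c₂⁰ = 1`.
3. **Outer optimization.** `A_crit` is chosen to minimize the inner
   residual sum of squares: a 25-point grid scan over the observed area
   range (guarding against local minima) followed by a bounded
   golden-section/Brent search between the best grid point's neighbours
   (`xatol` = 1e−8 of the area range). The refinement is never allowed to
   return a worse fit than the best grid point.
4. **Reporting.** The result carries the signed `p_crit = −p̃_crit`,
   `A_crit`, the shape parameters, the diagonal of the inner-fit
   covariance as variances (the uncertainty of `A_crit` itself is not
   propagated), the residual sum of squares, and a convergence flag.

A fit is flagged non-converged (never silently reported) when the
optimizer fails, the covariance is singular, or the fitted amplitude is
insignificant — `c₁` within 3σ of zero *or* below 5× the residual rms.
The second rule matters: on a featureless noisy curve the optimizer can
park a tiny spurious knee with deceptively small formal variance. Only
when every candidate fit raises does the estimator raise, with
per-candidate diagnostics.

Fit-quality metric: residual sum of squares with uniform weights. The fit
window is whatever survives preprocessing; the contact threshold is the
only windowing rule and is configurable (sensitivity to it is part of the
test surface).

## Dependence laws, phase diagrams, non-dimensional constants

Critical pressures from a sweep over one geometric parameter are fitted
with:

* `−p_crit(d) = A d^B + C` — defaults `A = 2.25e4 Pa`, `B = −2.20`,
  `C = 4.37e2 Pa` (sweep `d ∈ {3,…,6}` at `γ = 0.06`, `l = 1.1`);
* `−p_crit(γ) = Aγ³ + Bγ` — defaults `A = 2.53e6 Pa`, `B = 3.14e4 Pa`
  (`γ ∈ {0.05,…,0.09}` at `d = 3`, `l = 1.1`); note `B` carries units of
  Pa here but is a pure exponent in the d-law;
* `−p_crit(l) = A tanh(Bl) + C` — the published values `A = 1.90e7 Pa`,
  `C = −1.90e7 Pa` cancel to their printed precision, so the physically
  meaningful plateau `A + C` is unrecoverable from them. Evaluating the
  law with such parameters emits `IllConditionedParametersWarning` (the
  value returned is cancellation noise with the wrong sign). The fitter
  still supports the law and reports the A–C estimate correlation and the
  fitted plateau as conditioning diagnostics.

Each fitted law, evaluated on a grid, is the phase boundary between the
unbuckled and buckled states in the (parameter, `p_intr`) plane.

The non-dimensional transforms `p̂ = p_intr(1−ν²)/E · l⁻²γ⁻¹d` and
`Â = A l/(πr²)` (exactly invertible) collapse tube laws of different
geometries approximately onto one curve. Pooling the critical points of
all analyzed tubes gives the general constants as mean ± standard
deviation of each set; the population sd (`ddof = 0`) is used by default
since the set is the complete collection of analyzed tubes, with `ddof`
configurable.

The thin-shell (von Mises) two-lobed buckling formula is provided for
comparison; over the studied ranges it overestimates the collapse
pressure magnitude (thin-shell theory, no pre-stretch), approaching the
elastic-ring value `2Eγ³/(1−ν²)` as `d → ∞` (the end-support correction
decays as `(4d/π)⁻²`, reaching 1% agreement around `d ≈ 70`).

## Cross-section areas

Perimeter traces `(θᵢ, rᵢ)` of star-shaped sections are integrated as
circular wedges, `A = ½ Σ rᵢ² Δθᵢ`. The `closed=True` default includes
the wrap-around wedge between the last and first sample — exact for
constant radius at any sampling — while `closed=False` reproduces the
open sum to `N−1` that FEM post-processing sometimes uses; the open sum
is always ≤ the closed one. Angles are normalized to `[0, 2π)` and sorted
on ingestion (FEM exports are unordered); angles closer than 1e−12 rad
are rejected as duplicates. On uniform grids the wedge sum is a periodic
trapezoid rule and converges spectrally for smooth shapes; `O(N⁻²)` is a
safe general bound. Parametric fixtures: circle, ellipse
(`r = ab/√(b²cos²θ + a²sin²θ)`, default axis ratio 0.99 — the seeding
eccentricity used to control the buckling direction), and the two-lobe
mode `r = r₀(1 − ε cos 2θ)` with `ε ∈ [0, 1)` (closed-form area
`πr₀²(1 + ε²/2)`, used as the test oracle).

## Synthetic tube-law generator

The generator emulates what a FEM collapse run produces, with known
ground truth:

* **Ramp**: `p_max = 8000 Pa`, `τ = 20 s`, `Δt = 0.1 s` by default — 200
  samples at a 40 Pa pressure resolution, matching the production setting
  of the study it emulates (a 4000 Pa/10 s variant gives the 400 Pa/s
  sensitivity case). Samples run `t_j = jΔt`, `j = 1..M`, so `p̃ > 0`
  everywhere; any `p̃ = 0` sample would be skipped and counted.
* **Knee**: the saturating Landau model itself, with ground truth
  `p_crit_true` (from the d- or γ-dependence law for sweeps),
  `Â_crit = 0.924` (the general non-dimensional area constant),
  `β = 0.5` (mean-field), `c₂ = 1.5`, and `c₁ = 1 − Â_crit` so that the
  unloaded area sits at `Â ≈ 1`: areas are generated in units of the rest
  cross-section after incompressible pre-stretch, `πr²/l`, which makes
  the normalized area coincide with `Â`.
* **Contact**: a smooth lower saturation at `Â_contact = 0.25` via a
  softplus blend of width 0.02 (normalized units). With the default
  `c₁ = 0.076` the tanh branch bottoms out near `Â_crit − c₁ ≈ 0.85`, so
  contact never binds and the defaults exercise the knee, not the
  contact regime; deep-collapse configurations (larger `c₁`) make the
  saturation active and are used to test contact truncation.
* **Noise**: additive Gaussian area noise, sd 0.002 in normalized units —
  small compared to the knee amplitude 0.076, large compared to machine
  precision, a plausible FEM discretization-error scale. One
  `numpy` generator seeded per curve; the seed is recorded in the curve
  metadata, making fixtures bit-reproducible.
* **Sweeps**: defaults `d ∈ {3, 3.5, …, 6}` (7 tubes), `γ ∈ {0.05, …,
  0.09}` (5), `l ∈ {1.1, …, 1.8}` (8), all sharing the base triplet
  `(3, 0.06, 1.1)` — 20 tube laws over 18 distinct triplets. Per-curve
  seeds derive from a base seed via `SeedSequence`. The l-sweep *requires*
  explicit knee pressures: the published l-law is ill-conditioned, and
  the package refuses to manufacture ground truth from it. Where an
  l-sweep is needed internally (tests, the acceptance script), knee
  pressures are derived from the general non-dimensional pressure
  constant inverted at the base geometry,
  `p_crit(l) = −0.07 · E/(1−ν²) · l²γ/d` — the only printed source of an
  l-dependence magnitude; the fixed `(d, γ) = (3, 0.06)` is taken from
  the other sweeps' base by continuity, passed explicitly.
* **Default radius** `r = 5 mm`: absolute radii never enter the headline
  quantities (they cancel in `Â`); the value only sets absolute areas.

What the generator does *not* emulate: mesh-dependence and solver
residuals, the virtual contact plane, post-contact dynamics, asymmetric
or higher-lobed buckling modes, pressure-dependent noise, or any fluid
flow. Passing recovery tests therefore demonstrates that the estimator is
correct and robust *for tube laws of the assumed shape with additive
Gaussian noise* — not that FEM or experimental curves follow that shape;
that evidence lives in the study the model is drawn from.

## Numerical choices and conventions

* Sign convention: all public critical pressures are signed (negative)
  intramural pressures; `magnitude()` gives positive values. SI units
  throughout; non-dimensional quantities unitless.
* Dependence fits use `curve_fit` with data-driven starts (log–log slope
  for the power law, linear least squares for the odd cubic); degenerate
  data (all-equal pressures) yield a `degenerate`-flagged fit with
  singular covariance rather than an exception.
* Ramp sample count uses `floor(τ/Δt + 1e−9)` to absorb binary float
  round-off (`20/0.1` is 199.999… in floating point).
* CSV headers are unit-bearing (`p_intr_pa`, `area_norm`/`area_m2`) so
  files self-describe their normalization; readers sort shuffled rows by
  time with a warning and reject non-monotone pressures, all-zero areas
  and missing columns with row-numbered schema errors. Result JSONs embed
  the seed and a config hash.
* Non-dimensionalizing a fitted critical area assumes the curve's
  normalization base is the pre-stretched rest area `πr²/l` (exact for
  generated curves; for absolute-area inputs the transform is applied to
  the areas directly).

## Problem sizes

Defaults were chosen so a full pipeline is quick on one core: a single
estimation (25-candidate scan + refinement over 200-sample curves) takes
~0.5 s; the 20-tube default study runs in ~12 s; the acceptance summary
(two 20-tube analyses plus deterministic checks) in ~30 s.

## Known limitations

* The estimator assumes a single knee; multi-stage collapses or
  non-monotone tube laws are out of scope (the contact region is cut, not
  modelled — the contact critical pressure is deliberately deferred).
* Mean-field exponents only; no fluctuation corrections.
* The published l-law remains unusable for prediction at its printed
  precision; this package reports it honestly rather than guessing the
  lost plateau.
* The von Mises comparison uses the formula's original assumptions
  (thin shell, no pre-stretch); it is a reference line, not a fit.
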