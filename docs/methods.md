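# Methods

## Scope and model

The package characterizes soft fiber-reinforced elastomer coupons tested
in uniaxial tension.  The constitutive description is incompressible
isotropic hyperelasticity: a strain-energy density ψ(I₁, I₂) with
Cauchy-Green invariants I₁ = Σλᵢ², I₂ = λ₁²λ₂² + λ₂²λ₃² + λ₃²λ₁²,
I₃ = Πλᵢ² = 1.  Incompressibility is assumed throughout (silicone
elastomers and most soft tissues are very nearly volume-preserving);
under uniaxial load with traction-free lateral faces it forces
λ₂ = λ₃ = λ^{-1/2}, and the axial Cauchy stress follows from
σ₁ = λ₁ ∂ψ/∂λ₁ − λ₃ ∂ψ/∂λ₃.  For the three implemented energies
(Mooney-Rivlin, Humphrey, Veronda-Westmann — see the README table) this
yields the closed forms σ(λ) = 2(λ² − 1/λ)(∂ψ/∂I₁ + (1/λ)∂ψ/∂I₂).
`stress_from_energy_numeric` evaluates the derivative route by central
finite differences of ψ(λ₁, λ₂, λ₃) and is kept strictly independent of
the closed forms; their agreement (relative 10⁻⁶ at step 10⁻⁵) is the
module's core correctness check, and it also pins the bracketing of the
Veronda-Westmann stress (the c₁c₂ prefactor multiplies the whole
bracket, including the −1/(2λ) term).

Transversely isotropic formulations, biaxial loading and strain-rate
dependence are out of scope: fibers enter only through the specimen
metadata and the synthetic family, and each curve is fitted with an
isotropic model as is standard for this kind of coupon-level
characterization.

## Data reduction

Machine records are load (N) versus crosshead extension (mm).
Engineering stress uses the undeformed cross-section (width × thickness)
and engineering strain the gauge length, both from the per-specimen
geometry sidecar; units are fixed internally to N, mm, MPa with
converters at the I/O boundary.  The reduction then applies, in order:

1. **Slack trim.** The leading run of samples with stress ≤ 0 is
   removed (the coupon is not yet taut).  An interior dip to ≤ 0 is
   retained but warned about — it usually signals grip slip, not slack.
2. **Yield trim.** Everything after the global stress maximum is
   dropped.  "Yield" is deliberately operationalized as the global peak:
   for soft elastomer coupons the load drop at failure or slip is abrupt
   and the peak is a robust, parameter-free cut; ties resolve to the
   first peak.
3. **Origin shift.** The first retained sample is translated to (0, 0).
   Each of steps 1–3 is idempotent.
4. **True conversion.** σ_true = σ_eng(1+ε_eng), ε_true = ln(1+ε_eng),
   valid for ε_eng > −1; exactly invertible, which the generator uses.
5. **Cubic trendline.** An unconstrained least-squares cubic of true
   stress on true strain.  The intercept is not forced to zero (the data
   are already origin-shifted, so it stays small); R² below 0.99 warns
   rather than fails, and zero-variance data yield a flagged NaN.
6. **Standardized grid.** The cubic is evaluated at ε = h, 2h, … with
   h = 0.01 by default, capped at ε = 1 *and* at the observed strain
   maximum — the polynomial is never extrapolated beyond the data it was
   fitted on; specimens that fail before ε = 1 simply produce shorter
   curves.
7. **Stretch axis.** λ = 1 + ε applied to the standardized true-strain
   axis, so the default curves live on λ ∈ (1, 2].  The kinematically
   exact alternative λ = exp(ε_true) is available via
   `PipelineConfig(stretch_map="exp")`; the linear map is the default
   because it is the conventional plotting/fitting axis for these
   materials and keeps λ ∈ [1, 2] aligned with a strain range of [0, 1].

A consequence of the unconstrained cubic is that the reduced curve's
stress at the smallest grid node converges (as h → 0) to the cubic's
intercept rather than exactly to zero; the origin shift keeps that
intercept small (≲ 1–2% of peak stress in practice), and the tests
assert both the convergence and the smallness.  The per-stage sample
counts are logged and returned so trims can be audited exactly.

## Fitting

The objective is the plain (unweighted) sum of squared stress
differences on the standardized grid, restricted to λ ≤ 2.  The
minimizer is SciPy's bounded trust-region least squares with tight
tolerances and |c₁| ≤ 100 MPa, |c₂| ≤ 50 (the latter keeps the
exponential far from overflow on λ ≤ 2).  Starts are deterministic:

* a sign × magnitude grid c₁ ∈ ±{10⁻⁵ … 10⁻²}, c₂ ∈ ±{10⁻³ … 1},
  screened by initial SSE so only the best corners launch full solves;
* the exact linear least-squares solution for Mooney-Rivlin (the model
  is linear in both coefficients — the nonlinear solver then only
  polishes);
* for the exponential models, a profile over a fixed c₂ grid with the
  conditionally optimal c₁ (linear given c₂), plus a start from the
  small-stretch slope identity (initial slope = 6c₁c₂ for Humphrey,
  3c₁c₂ for Veronda-Westmann).

The profile starts matter because the exponential models degenerate as
c₂ → 0: only the product c₁c₂ is strongly identified and the SSE valley
is extremely flat along it.  With the profile starts the fitter recovers
even a near-degenerate truth (c₂ = 10⁻³) from noiseless data to printed
precision.  The reported result is the lowest-SSE solution; the attained
minimum, not the path to it, is the contract, and the whole procedure is
seed-free and deterministic.

R² is the ordinary coefficient of determination with mean-centered total
sum of squares (negative for fits worse than the mean predictor, NaN
with a warning for zero variance).  A fit is `accepted` iff
0.99 < R² ≤ 1.  Acceptance is a property of the fit, not of the model:
on strongly exponential curves (the stiffest members of the synthetic
family, generated with c₂ ≈ 0.46–0.56) Mooney-Rivlin tops out near
R² ≈ 0.98 and is honestly reported as not accepted — a two-parameter
energy that is linear in the invariants cannot track an exponential
stress over λ ∈ [1, 2] to the gate.

## Low-stretch modulus

The tangent modulus at λ = 1 summarizes stiffness for FVF/orientation
comparisons.  It is estimated from the points with λ ≤ 1 + w (default
window w = 0.05) by a through-origin fit.  Two estimators are provided:

* `origin-quadratic` (default): fit σ = k(λ−1) + b(λ−1)² through the
  origin and report k.  The quadratic term absorbs the curve's leading
  curvature, leaving a bias that is third-order in w.
* `origin-secant`: through-origin straight line, the direct analogue of
  drawing a tangent from the origin on a plotted curve.  Its bias is
  first-order in w — about 0.75·w·σ″(1)/σ′(1) — which for
  Veronda-Westmann (where σ″(1)/σ′(1) = 2·c₂-independent ≈ 2) is ~1.5%
  already at w = 0.02.

The quadratic estimator is the default precisely because of that
Veronda-Westmann bias: it reproduces the analytic limits 6(c₁+c₂),
6c₁c₂ and 3c₁c₂ to well under 1% at w = 0.02 for all three models,
while remaining exact on linear curves for any window.  Both estimators
are model-free (they never use the fitted coefficients).

On pipeline-reduced (cubic-standardized) curves the modulus inherits the
trendline's origin error, which is comparable to the true signal inside
a 0.05 window for very soft specimens; modulus values in cohort reports
should therefore be read as protocol-consistent summaries, while the
analytic-limit validation uses directly generated curves.

## Synthetic specimens

The generator exists so that every stage is testable against known
truth; its defaults emulate the test conditions of the physical coupons
it mimics, and they are fixed rather than tuned:

* geometry: composite coupons 30 × 10 × 3 mm (matrix-only coupons
  49.5 × 10 × 2.5 mm), per the fabrication ranges of such specimens;
* crosshead rate 0.4 mm/s, recorded as metadata; sampling 25 samples/mm
  (10 Hz at that rate);
* a slack region of strictly negative loads bounded by the machine
  preload (< 0.1 N), placed so that contact falls half a sample before
  the first ramp point — at zero noise the slack trim then removes
  exactly `slack_points` samples;
* the loading ramp inverts the reduction exactly (truth curve on the
  λ = 1 + ε_true axis → engineering quantities → load/extension), so
  end-to-end discrepancy measures only the cubic-approximation error
  (≤ 2% of peak stress on the default grid);
* a post-yield tail decaying linearly to 30% of peak over ~10%
  additional extension, strictly below the peak so the yield trim
  removes exactly the injected tail;
* Gaussian load noise scaled to peak load, from one seeded generator;
  zero-noise records are seed-independent.

The composite family interpolates Humphrey-model parameters between the
published matrix (c₁ = 2·10⁻², c₂ = 10⁻³) and fiber (c₁ = 1.6·10⁻³,
c₂ = 0.555) anchors.  An effective fiber volume fraction
f_eff = FVF·[(1−ε_t)·cos⁴θ·S + ε_t] carries the orientation dependence
(cos⁴θ is the leading uniaxial stiffness scaling of an off-axis fiber),
a small transverse residual ε_t = 0.05, and monotone fiber-count/spacing
knobs S (gain 0.08 per extra fiber, loss 0.02 per mm spacing; S = 1 at
the single-fiber zero-spacing default so the FVF = 1 endpoint is the
fiber anchor exactly).  The initial stiffness 6c₁c₂ is interpolated
log-linearly in f_eff and c₂ linearly, with c₁ derived.  Interpolating
the stiffness rather than c₁ directly is essential with these anchors:
c₁ *decreases* from matrix to fiber while c₂ increases, and log-linear
c₁ with linear c₂ produces a spurious stiffness bump that overshoots the
fiber curve at mid f_eff.  With the stiffness-based rule both
interpolants are monotone, so family stresses increase pointwise in
f_eff and every member lies inside the matrix–fiber envelope by
construction.  The rule is an explicit synthetic stand-in — it encodes
the qualitative orderings (FVF stiffening, 0° ≥ 45° ≥ 90°, transverse
response insensitive to fiber count) and makes no micromechanical claim
(no shear-lag or Halpin-Tsai content); passing the family tests shows
the pipeline resolves such orderings, not that real composites follow
this interpolation.

What the synthetic records do *not* emulate: strain-rate effects,
viscoelastic hysteresis or cyclic loading, grip slip mid-test,
machine compliance, and specimen-to-specimen fabrication scatter.
Validation on them therefore demonstrates correctness of the reduction
and identification machinery, not robustness to every experimental
artifact.

## Numerical choices and problem sizes

* Standardized grid interval 0.01 over strain (0, 1] — 100 nodes; fits
  use λ ∈ [1, 2].
* Finite-difference oracle step 10⁻⁵ (second-order; Richardson-verified).
* Optimizer tolerances 10⁻¹⁵ (xtol/ftol/gtol), ≤ 400 function
  evaluations per start, one polishing pass from the incumbent.
* Validation battery: 7 coefficient rows × 3 models, noiseless
  generate-and-refit on the 100-node grid (~5 s total); Monte-Carlo
  noise study: 24 seeded replicates at 1%-of-peak noise.
* Fixture battery: 10 specimens (2 pure + 5 FVF levels + 3
  orientations), ~1400 samples per record.
* Degenerate inputs: zero stress variance → NaN R² with warning; fewer
  than 4 distinct strains → rank error; all-nonpositive loads → empty
  curve error; per-specimen failures in batch runs are isolated and
  summarized, never fatal to the cohort.

## Known limitations

* The cubic trendline is the protocol's standardization device, not a
  physical model; curves that are strongly exponential over a long
  strain range can push its origin error toward the 1–2% level, which
  dominates the end-to-end error budget and the small-window modulus.
* Raw records must be a single monotone loading ramp; unloading or
  cyclic segments are rejected by the monotonicity invariant rather
  than segmented.
* Coefficient units follow the stress units of the curves being fitted
  (MPa here); the reference coefficients are treated as MPa-consistent.
* The ``±`` signs on published coefficient ranges are ambiguous;
  coefficients are stored signed, and range comparisons are made on
  magnitudes only.
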