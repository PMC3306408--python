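# Methods

## Models

Let `x ≥ 0` be dose and `y` a continuous response (e.g. root length).
The three nested mean functions are

* 4-parameter log-logistic: `y = c + (d − c)/(1 + (x/e)^b)`
* Brain–Cousens (BC): `y = c + (d − c + f·x)/(1 + (x/e)^b)`
* Cedergreen (CRS): `y = c + (d − c + f·exp(−x^(−a)))/(1 + (x/e)^b)`

with `d` the control mean, `c ≥ 0` the lower asymptote, `b` a
slope-type parameter, `e > 0` a dose scale, `f` the hormesis parameter
(`f > 0` necessary for hormesis) and `a > 0` the CRS low-dose shape.
At `x = 0` both hormetic terms vanish and the model is evaluated at
its analytic limit (`d` for `b > 0`); the logistic exponent
`b·(ln x − ln e)` is clamped at ±700 before exponentiation so extreme
slopes never produce non-finite responses. Setting `f = 0` reduces
both hormetic families to the log-logistic *exactly*, which the test
suite asserts to machine precision.

A structural point worth knowing: `exp(−x^(−a))` vanishes faster than
any power of `x` as `x → 0`, while the logistic decline `(x/e)^b`
vanishes only polynomially. Every CRS curve therefore dips
infinitesimally below `d` at sufficiently small doses. A "pre-hormetic
drop" is only reported when the dip exceeds a configurable depth
(default 0.1% of `d`, `min_depth_rel`).

## Reparameterization

Practitioners need the dosages implied by a fitted curve, with
standard errors:

* `ED_K`: dose giving K% inhibition. Defining relationship
  `y(ED_K) = level(K)`; two level conventions are supported,
  `relative_to_control` (`(1 − K/100)·d`, the default) and
  `relative_to_range` (`c + (1 − K/100)(d − c)`). They coincide when
  `c = 0` (the usual constraint in this assay class) and at `K = 0`.
  The relationship is linear in `d`, giving the closed form
  `d = (c(1 − D) − s)/(1 − (1 − K/100)·D)` with `D = 1 + (ED_K/e)^b`
  and `s` the stimulation term at `ED_K` (`f·ED_K` for BC,
  `f·exp(−ED_K^(−a))` for CRS).
* `LDS`: the `K = 0` special case (`y(LDS) = d`).
* `M`: stationary point, `dy/dx(M) = 0`, linear in `f`:
  `f = (d − c)·b·L / denom` with `L = (M/e)^b` and
  `denom = M(1 + L − bL)` for BC,
  `a·M^(−a)·g·(1 + L) − g·b·L` for CRS (`g = exp(−M^(−a))`).
  `b = 0` makes the logistic term flat and the closed form degenerate
  (error). A negative implied `f` means the requested M is not a
  genuine maximum.

Substituting the closed form back into the mean function yields a
model whose free parameters include the target dosage; its curve set
is identical to the natural family's (asserted on dose grids), so the
natural and reparameterized fits reach the same optimum SS and the
dosage estimate inherits a Wald standard error from the fit
covariance. The closed forms were derived symbolically and are
validated by the curve-set-equivalence and defining-property tests
rather than transcribed from any particular software syntax.

An independent numeric oracle (`functionals_from_natural`) extracts
the same functionals from natural parameters: M by grid bracketing
plus bounded golden-section/Brent maximization (polished on the
analytic dose-derivative when it brackets a sign change), LDS and
ED_K by bracketed root finding on the inhibitory branch (`x > M`),
with the bracket expanded geometrically ×10 from `max(10e, ...)` up
to `10^6·e` before declaring failure. ED_K and LDS are always taken
right of M; pre-hormetic roots are handled only by the dedicated drop
quantification, which exploits the multi-root structure
intentionally.

## Fitting

The objective is `Σ w_i (y_i − μ(x_i; θ))²`. The default weights are
the inverse replicate standard deviation at each dose
(`inverse_sd`), the variance-stabilizing convention of this assay
literature; `inverse_variance` and unweighted fits are available
because the weighted-regression objective is a convention choice, not
a law. Weighting requires ≥ 2 replicates per dose; a dose with zero
replicate SD receives the smallest positive per-dose SD (logged) so
no weight becomes infinite.

Minimization uses scipy's trust-region reflective least squares — a
damped (Levenberg-type) iteration that honors the box constraints
`c ≥ 0`, `e > 0`, `a > 0`, target dosages > 0 natively — with
`ftol = xtol = 1e-12` (relative SS reduction; strict tolerances keep
the natural and reparameterized optima equal to ~1e-8 relative SS)
and at most 1000 iterations per free parameter. `b` is *not*
constrained above 1 for the BC family. The covariance is
`s²(JᵀWJ)⁻¹` via SVD of the weighted Jacobian at the optimum, with
`s² = SS_res/df_res`; a singular Jacobian raises a rank-deficiency
error naming the weakest parameter direction (e.g. `a` when `f ≈ 0`
makes it unidentifiable).

Starting values follow the bioassay protocol: `d` = control mean,
`c = 0`, `e` = 0.8 × the dose whose mean is nearest 50% of control,
and a deterministic ladder of presets — `f` ∈ {0, 1, 10, 100} scaled
by the observed maximum stimulation above control (outermost), then
`a` ∈ {0.1, 0.5, 1}, then `b` ∈ {1, 2, 3} — walked until a fit
converges; the attempt trace is recorded on the result. A
reparameterized fit is seeded from a converged pilot natural fit with
the target dosage seeded by the numeric oracle, mirroring the
practice of refitting each target from the established curve.

When the CRS `a` cannot be freely estimated, `fix_a_profile` refits
over the grid a ∈ [0.07, 1.75] in steps of 0.02 (85 values; only the
range and the smallest-SS_res criterion are standard, the step is
this package's choice) and keeps the smallest-SS_res fit; a fixed `a`
is excluded from the degrees-of-freedom accounting.

## Inference

Intervals are t-based with `df = df_res`, matching mainstream
nonlinear-regression defaults (a knob in principle; t chosen
throughout, including for predicted responses). Hormesis is declared
significant when the two-sided CI for `f` excludes zero with
`f̂ > 0` — the two-sided-CI formulation of the one-directional
question, applied identically to natural and ED_K-parameterized fits.
Predicted responses use the delta method with central-difference
gradients; `y_max = y(M̂)` uses the same code path, and because M̂ is
a stationary point the gradient at fixed dose is exact for it (the
envelope argument), including the version expressed as a percentage
of `d` with full covariance propagation.

Pre-hormetic drop: the dip of a fitted CRS curve on `(0, M)` is
located numerically (bounded minimization polished on the analytic
slope; root of `y = d` for LDS_min). CIs for M_min and LDS_min come
from refitting the M- and LDS-parameterized models *started at the
pre-hormetic roots* — the defining relationships have multiple
solutions there, and the refit converges to the same curve in a
chart whose coordinate is the pre-hormetic dose; the refit is
accepted only if it lands on that root with the original SS_res,
otherwise a delta-method fallback (implicit re-solving of the
defining equation under parameter perturbations) is used and the
source recorded. The drop is called significant when the CI of
`100·y_min/d` excludes 100 — an exploratory device, labeled as such.

## Model comparison

The lack-of-fit F test decomposes the weighted `SS_res` about
per-dose means into lack-of-fit and pure-error parts
(`df_pure = n − #doses`, `df_lof = #doses − #free parameters`).
Pseudo-R² (`1 − SS_res/SS_corrected`, weighted) is reported as a
supplemental index only — it can flatter a structurally wrong model.
The CI-overlap screen (does each model's CI cover the other's point
estimate?) is an indication, not a test; it does not hold a 5%
type-I rate. Relative bias is `100(estimate₂ − estimate₁)/estimate₁`
with the better-fitting model (lower `SS_res/df`, overridden by
hormesis significance) as baseline.

Case classification: case 1 (neither suitable) requires no
significant hormesis from either family *and* both failing a
residual-pattern screen; cases 2/3 when only one family finds
significant `f`, or both do but one fits better beyond margins
(default |ΔPseudo-R²| ≥ 0.01 or SS_res/df ratio outside [0.9, 1.1],
both configurable); case 4 (equally suitable) otherwise. The human
judgment of "graphical agreement" cannot be automated; its surrogate
here is a Wald–Wolfowitz runs test on the signs of dose-ordered
residuals (normal approximation), clearly labeled a surrogate in
reports.

## Synthetic data and what it does(n't) show

The generator emulates replicated germination-bioassay structure: a
geometric dose series with an untreated control, a hormetic truth
curve, and independent Gaussian noise with per-dose SD proportional
to the local mean (5% of control at the control, floored at 1% of
control) so inverse-SD weighting is actually exercised. Negative
draws are truncated at zero (measurement floor), counted, and rare
(< 1% of observations) in all default scenarios. The default
scenario is a CRS truth `(c=0, d=100, b=2, e=10, f=50, a=1)` on doses
{0, 0.1, 0.3, 1, 3, 10, 30, 100} with 5 replicates. Per-simulation
seeds derive from `(seed, sim_index)` seed sequences, so experiments
are exactly reproducible.

Real bioassay data differ in ways the generator does not model:
non-Gaussian and possibly skewed replicate variation, plate/dish
nuisance structure, correlated errors within dishes, and dose designs
chosen adaptively. Passing Monte-Carlo checks therefore validate the
estimation machinery under its own assumptions, not robustness to
those violations.

Monte-Carlo scale in the shipped tests and acceptance script: 20
scenarios × 6 fits for the equivalence battery, 300 simulations for
ED50 recovery/coverage, 500 for type-I calibration, 100 for the
misspecification pattern, 1000 bootstrap draws for the y_max SE —
sizes chosen to make the statistical bands informative while keeping
a full run in the minutes range on one CPU.

The type-I calibration fits the Brain–Cousens model to monotone
log-logistic truth; BC is used because it needs no fixed-`a`
protocol, and the Wald-type test is expectedly conservative (observed
rejection ≈ 1–3% at nominal 5%). The equivalence battery fixes the
CRS `a` at its generating value — the preset-`a` device of the
fitting protocol — because a freely estimated `a` is occasionally
rank-deficient on 40-observation designs, which is a property of the
design, not of the reparameterization being tested.

## Known limitations

* Wald/t intervals only; no profile-likelihood intervals or
  simultaneous bands.
* No 5-parameter log-logistic, Weibull, or switching-function
  alternatives; no mixed-effects or robust fitting; continuous
  responses only.
* The An–Johnson–Lovett family (useful when both models fail, e.g.
  very steep inhibition with few hormetic doses) is out of scope.
* The CI-overlap screen and the y_min significance rule are
  indications, not calibrated tests.
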