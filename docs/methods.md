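# Methods

This note documents the models, conventions and numerical choices behind
toxmix, and what the synthetic-data generators do and do not emulate.

## Dose–response model

Single-compound acute mortality is modelled as
logit *F*(*c*) = α + β·log₁₀ *c* with β > 0 for a toxicant. Base-10 logs
are used throughout; the choice is conventional for concentration–response
work and does not affect LC values. Two estimators are exposed:

- `binomial_glm` (default): logistic GLM on well-level (dead, alive)
  counts, i.e. binomial maximum likelihood, via statsmodels. Preferred
  because it weights concentrations by their information content and
  yields a proper parameter covariance.
- `empirical_logit_ols`: ordinary least squares of empirical-logit
  proportions on log₁₀ concentration. Boundary proportions (0% or 100%
  mortality) are replaced by (k + 0.5)/(n + 1) before the transform, since
  the logit is undefined at 0 and 1. This mirrors transformed-proportion
  regression as historically practiced; the two estimators agree closely
  on balanced designs away from the boundaries.

Controls (concentration 0) are excluded from fitting and no
background-mortality (Abbott) correction is applied: the assay design
assumes negligible control mortality, and the generators enforce it.

LC*x* = 10^((logit(*x*/100) − α)/β). Its standard error comes from the
delta method — the gradient of that mapping applied to the (α, β)
covariance — and the 95% CI is the symmetric Wald interval
value ± 1.96·SE on the arithmetic concentration scale. Symmetric
arithmetic-scale intervals were chosen over log-scale intervals to match
the reporting style of the LC tables this package reproduces; simulation
at the default design (5 concentrations spanning logit ±2.5, 3 wells of
100 cells) shows 95% CI coverage of 95–96%, inside the 93–97% band the
acceptance suite demands.

Reported R² is computed on the logit scale against empirical-logit
observations for both estimators, so the two methods are comparable.

When only (LC20, LC50) pairs are available — the usual situation when
reusing published tables — `curve_from_lcs` reconstructs the unique curve
through both points. Note the reconstruction inherits the rounding of the
printed LC values; on the Cd + Zn grid this leaves up to ~6 percentage
points of discrepancy against the published expected-mortality column at
the worst cell (median ~2), which is why reproduction checks on those
cells carry a few points of tolerance.

## Toxic units and effect summation

1 TU = the compound's own 24 h LC50, so a (TU₁, TU₂) dose is directly
comparable across compounds. The effect-summation expectation adds the
single-compound mortality fractions at each component's concentration and
caps at 100%. Effect summation is deliberately naive — it ignores that
effects cannot literally add — but it is the classical screening
reference for TU designs and saturates exactly at (1, 1) TU since each
component contributes 50%.

Interaction calls use a one-sample two-sided t-test of the observed
replicate mortality (mean, SD, n) against the expectation as a point
value, at α = 0.05. The expectation's own uncertainty is ignored: its
provenance in summary tables is typically unclear, and treating it as
fixed keeps the test well-defined. Zero observed SD (e.g. all replicates
at 100%) is treated as an exact observation — any difference from the
expectation is then significant. Classification labels are sensitive to
these conventions and should be read as a screening call, not a precise
inference.

## Response surfaces

Both references reduce exactly to the marginal curve when one
concentration is zero, and CA satisfies the sham-combination identity
(mixing a compound with itself reproduces its own curve) to 1e-8, which
the test suite enforces.

Deviation functions (parameters *a*, *b*) multiply into the references
via exp(*G*):

- CA: Σᵢ cᵢ/ECᵢ(*F*) = exp(*G*). The root in *F* is found on
  [1e-9, 1 − 1e-9] by vectorized bisection (60 halvings, resolution far
  below the 1e-8 identity tolerance). The toxic-unit fractions
  zᵢ = (cᵢ/ECᵢ(F))/Σⱼ(cⱼ/ECⱼ(F)) feeding *G* are re-evaluated at every
  candidate *F*, so the deviation is computed at the mixture's own effect
  level. If an extreme deviation pushes the root outside the bracket the
  prediction saturates at the bracket edge (effectively 0 or 1 mortality);
  this is the correct limit of the model and keeps the SSE surface
  continuous during optimization.
- IA: *F* = 1 − [(1−F₁)(1−F₂)]^exp(−*G*), with zᵢ evaluated at the
  IA-predicted effect level by fixed-point iteration started from the
  reference prediction (plain iteration, damped after 30 steps as a
  cycling safeguard, tolerance 1e-12).

Sign convention: *a* < 0 ⇒ synergism under both references (exp(*G*) < 1
shrinks the CA dose requirement; exp(−*G*) > 1 shrinks the IA survival
product). The DL dose level is TUtot = c₁/LC50₁ + c₂/LC50₂, so with
*b* = 1 the deviation changes sign exactly at the combined LC50 level.
The DR asymmetry parameter *b* attaches to z₁ of the first-listed
component; component order therefore matters and is recorded by the CLI.
The exp(−*G*) coupling for IA and these exact G-forms are package
conventions — published parameter values obtained with other
implementations of the same ideas are comparable in sign and rough
magnitude, not digit-for-digit.

### Fitting and model selection

The error model is Gaussian and homoscedastic on the mortality fraction:
fits minimize SSE, equivalently maximize the profile Gaussian likelihood.
Free parameters are the deviation (*a*; *a*, *b*) and optionally the four
single-curve parameters (`refit_singles`, the default for reproducing
published surface tables, since the original analyses refit singles
jointly). Optimization is Nelder-Mead from a 5 × 5 start grid over
(*a*, *b*) ∈ {−10, −5, 0, 5, 10}²: every start is scored once, the four
most promising are polished (plus any seed handed down from a parent
model), with SSE tolerance 1e-10. Seeding each child from its parent's
optimum guarantees SSE never increases along the nesting ladder
reference → S/A → {DR, DL}.

Nested models are compared with χ² = *n*·ln(SSE₀/SSE₁) on df = number of
added parameters. With 16-point grids and Gaussian noise the empirical
type-I error at α = 0.05 sits within [0.03, 0.07] (checked over 500
simulated reference datasets). An SSE inversion (child worse than parent,
impossible at the true optima) floors the statistic at zero with a
warning rather than failing.

## Biomarker statistics

Technical triplicates are averaged into their biological replicate before
any test, avoiding pseudo-replication of the nested design. The battery
is Shapiro–Wilk per group (constant groups reported as degenerate, not
errors), Levene across groups, one-way ANOVA, and pairwise t-tests with
Bonferroni adjustment (raw p × number of comparisons, capped at 1) run
only when the omnibus test is significant. Correlations between endpoints
are Pearson R over treatment-level means — one value per endpoint pair
per exposure scenario, matching how such tables are reported — not over
raw replicates.

## Synthetic data

The generators emulate the acute design: 100 cells per well, 3 wells per
concentration, 3 biological replicates, zero control mortality, binomial
deaths per well. Default test concentrations are log-spaced so the
expected mortality spans ~8–92% (logit ±2.5), the range a well-designed
acute test covers. Mixture trials draw well-level binomial noise around a
chosen surface (Gaussian noise is available); biomarker panels couple
endpoint means through a shared latent factor loaded at √|ρ| so two
endpoints' treatment profiles correlate at ρ, with Gaussian replicate
noise on top (negative ρ is representable for exactly two endpoints).

What the generators do **not** emulate: solution-chemistry artifacts
(nanoparticle aggregation, dissolution, adsorption), time-dependence
within the 24 h window, between-replicate overdispersion beyond binomial,
control mortality, and count-valued biomarker noise. Passing recovery
tests therefore demonstrate correctness of the estimators under the
stated statistical model, not robustness to those real-data features.

## Problem sizes used in the checks

Recovery and calibration checks run at deliberately moderate sizes chosen
to give stable Monte-Carlo estimates: 200 seeds for LC50 simulate–refit
recovery and CI coverage (at 300 cells per concentration), 500 simulated
datasets for likelihood-ratio type-I calibration (on the IA reference,
whose predictions are closed-form), and 10–40 seeds for the heavier
surface-selection loops. These sizes are the package's own defaults for
its validation suite.

## Known limitations

- Logit link only; probit/Weibull alternatives, hormesis and
  time-to-event models are out of scope.
- Binary mixtures only; no ternary designs or isobologram graphics.
- The Wald CI on LCx can misbehave for very steep curves or tiny designs;
  the delta method is first-order.
- Interaction calls from summary statistics inherit the printed rounding
  of means and SDs.
- The deviation-parameter scale is convention-dependent (see above);
  compare signs and model choices across implementations, not raw values.
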