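# Methods

## Scope and model

The package estimates the dose–response relationship between a continuous
lipid-ratio exposure `x` (non-HDLc/HDLc) and a binary short-term mortality
outcome in sepsis cohorts, under the working hypothesis that the
relationship is U-shaped on the logit scale. Three exposure models are
fitted and compared:

1. **One-line model**: `logit p = β0 + β1 x + γᵀz` — the conventional
   single-slope logistic model.
2. **Two-piecewise (hinge) model**: `logit p = β0 + β1 x + β2 (x − K)₊ + γᵀz`.
   The hinge term `(x − K)₊ = max(x − K, 0)` keeps the logit continuous at
   the turning point `K`; the slope is `β1` below `K` and `β1 + β2` above.
   The below-segment odds ratio is `exp(β1)`; the above-segment odds ratio
   `exp(β1 + β2)` gets its Wald interval from the delta method,
   `Var(β̂1 + β̂2) = V11 + V22 + 2 V12` (a reparameterised refit on the basis
   `{1, x, min(x − K, 0)}` is the equivalent cross-check, exercised in the
   tests).
3. **Penalized-spline smooth**: `logit p = f(x) + γᵀz` with `f` a cubic
   B-spline — the visual companion used to display the shape, not to test it.

`z` is the adjustment set (age, sex, weight, heart rate, lactate,
APACHE IV score, SOFA score, septic shock, infection site), expanded to
k−1 indicators against reference levels (sex: male; infection site:
pulmonary). Continuous covariates missing in more than 1% of rows get the
missing-indicator treatment: a binary was-missing column plus mean
imputation of the gaps. The 1% rule is strictly-greater; at or below it
the column is mean-filled without an indicator. The fill constant is the
observed mean — the indicator column carries the missingness signal
regardless of the constant, and the mean keeps the filled column's first
moment unchanged (an exact invariant in the tests). Rows with a missing
exposure are excluded (with a logged count) rather than imputed, and
multiple imputation is deliberately out of scope: the indicator method is
the analysis this package reproduces.

## Turning-point estimation

`K` is estimated by profile likelihood: the hinge model is refitted at
every candidate on a grid and the log-likelihood maximiser is kept (ties
broken toward the smallest candidate, with a warning). The default grid
runs from the 5th to the 95th percentile of the observed exposure in steps
of 0.1 ratio units, dropping candidates that would leave fewer than 20
observations in either segment. The step matches the one-decimal precision
at which turning points in this literature are reported; the quantile
window plus segment floor keeps every candidate fit identifiable.

The **likelihood-ratio test** compares the one-line model with the hinge
model at `K̂`: `Λ = 2(ℓ₂ − ℓ₁)` referred to χ²(1) — one degree of freedom
for the hinge coefficient, not counting the searched `K`. This is the
convention of the threshold-analysis software this field uses, and it is
anti-conservative: scanning the grid for the best-fitting knot inflates
the null rejection rate above the nominal α. The package documents and
measures this rather than correcting it (no Davies-type adjustment): under
a strictly linear-logit generator the acceptance suite records the
empirical rejection rate at α = 0.05 over 200 simulations of n = 2,000
(0.19 at the suite's seeds — roughly four times nominal). Users should
read a borderline LRT p-value accordingly.

The **bootstrap CI for K** resamples patients with replacement, reruns the
full grid search on each resample (the grid is recomputed from the
resample's own exposure quantiles), and takes percentile 2.5/97.5 limits
of the `K̂` distribution. Default B = 500; a minimum of 100 is enforced
because percentile limits from fewer resamples are not meaningful.
Resamples whose search fails (e.g. separation in a degenerate resample)
are dropped and counted; more than 10% failures aborts. Whether the
percentile interval covers `K̂` is checked and a pathological violation is
flagged rather than silently reordered. Empirical coverage at the default
study conditions (n = 2,000, B = 200, 50 replicates) sits inside [88%, 99%]
in the acceptance suite.

**Per-SD rescaling**: a per-unit odds ratio `OR` becomes `OR^s` with `s`
the full-cohort sample SD of the exposure; CI limits transform identically
(monotone map). The turning point and its CI are standardised as
`(K − x̄)/s` with the full-cohort sample mean and SD.

## Logistic engine

All maximum-likelihood fits use an in-package iteratively reweighted least
squares routine: start at β = 0, Newton steps with step-halving so the
Bernoulli log-likelihood never decreases, convergence when the maximum
absolute score is below 1e-8, cap of 100 iterations. The covariance is the
inverse observed information at the optimum; intervals and p-values are
Wald (matching the standard software output this style of analysis
reports; profile-likelihood intervals are not offered). There is no
penalisation: perfect separation is detected (single-column separation
up front; coefficient divergence during iteration) and raised as an error
naming the culprit, never silently shrunk. Rank-deficient designs are
rejected with the dependent columns listed. The engine is cross-checked
against statsmodels GLM coefficient-for-coefficient in the tests, and on
all-positive 2×2 data against the closed form `ln(ad/bc)` to 1e-8. The
profile search and bootstrap run the same IRLS through a stripped fast
path (preallocated design, hinge column updated in place, warm starts from
the neighbouring grid point); its profile values agree with the
full-featured fit to ~1e-13, which the suite asserts via an exhaustive
independent refit.

## Smooth dose–response

The smooth term is a cubic B-spline basis of dimension 20 with knots at
exposure quantiles and a curvature penalty, fitted as a penalized binomial
GLM (statsmodels `GLMGam`). The smoothing weight is chosen by minimising
AIC over a fixed log-spaced grid (10⁻³…10⁶, 19 points); AIC is used
because the effective degrees of freedom of a penalized fit make it the
natural likelihood-based selector here. The curve is reported as the
centered partial effect of the exposure (mean zero over the observed
exposure values) with a pointwise — not simultaneous — 95% Wald band from
the penalized-information covariance; its vertical anchoring is a
convention, since only differences in partial logit are identified.
Covariates enter linearly only. With the penalty driven to infinity the
fit collapses to the one-line model (the basis' penalty null space is
linear), and an unpenalized fit on the hinge basis `{1, x, (x − K)₊}`
reproduces the two-piecewise coefficients — both are asserted in the
tests and tie the smooth layer to the threshold layer. A shape diagnostic
reports the argmin of the smooth and the compressed sign pattern of its
numerical derivative ("−,+" is a U; derivative magnitudes under 1% of the
curve's slope scale count as flat). When the AIC-selected fit is wiggly
(small penalties win on large cohorts with rare events), the argmin remains
a stable summary while the sign pattern may pick up tail oscillations; the
sign pattern is a label, not an estimator.

## Descriptive layer

Baseline tables summarise each variable across exposure tertiles: mean ± SD
with one-way ANOVA for continuous variables (median (IQR) display for the
declared skewed set: lactate, SOFA), n (%) with Pearson chi-squared (no
continuity correction) for categoricals. ANOVA is applied to raw values
even for skewed variables, with Kruskal–Wallis available behind a flag —
the default mirrors the across-the-board ANOVA such cohort tables report.
Tertiles are nearest-rank cuts at ranks ⌊n/3⌋ and ⌊2n/3⌋ of the sorted
exposure, ties to the lower group: deterministic, permutation-equivariant,
and for n = 724 it yields the 241/241/242 split such cohorts print.
Binomial proportions get Wald intervals by default (z = 1.959964, clipped
to [0, 1]) — the method consistent with the published mortality CI this
package reproduces — with Wilson available behind a flag. 2×2 odds ratios
use `ad/bc` with the Woolf log-scale interval; zero cells are an error
with guidance, never silently continuity-corrected.

## E-values

For an odds ratio of a rare outcome (the ~6% mortality here) the OR is
taken as the risk ratio; protective estimates are inverted first, so
`E(OR) = E(1/OR)` exactly. `E = RR + √(RR(RR − 1))`. For common outcomes
the `RR ≈ √OR` approximation is applied first (flag). The CI E-value uses
the limit nearer the null and is exactly 1 when the interval crosses 1.
The headline E-value belongs to the above-threshold per-unit odds ratio
(1.28 → 1.88), the segment whose point estimate the rare-outcome formula
maps to that robustness bound.

## Synthetic cohort generator

The generator emulates the statistical shape of a 724-patient ICU sepsis
cohort with lipid-panel data:

- **Exposure**: lognormal truncated to [0.28, 10], parameters
  μ = 1.11390506, σ = 0.66836502 solved (offline, once) so the truncated
  law has mean 3.43 and SD 2.01 — the published moments. Only the range
  and moments of the real exposure are public; the lognormal shape is this
  package's choice of a realistic right-skewed ratio law.
- **Risk**: Bernoulli with `logit p = β0 + β1 x + (βₐ − β1)(x − K)₊ + Σ
  covariate terms`; defaults K = 3.3, `exp(β1)` = 0.60, `exp(βₐ)` = 1.28,
  β0 = −1.7154223 solved so marginal mortality is ~6% under the default
  exposure law. Deaths are drawn by comparing shared uniforms to the risk,
  so at a fixed seed raising a slope can only add deaths (a monotone
  coupling the property tests rely on).
- **14-day deaths** are a thinning of 28-day deaths with conditional
  probability 0.7 (a plausible default; published sources report the
  14-day analysis without counts).
- **Covariates**: marginals on the scale of the published baseline table
  (age ≈ N(66.7, 15.2) on [18, 89], weight ≈ N(85.5, 28), lognormal
  lactate and SOFA, 58.3% septic shock, six-level infection-site
  distribution, …), with **zero effect on the logit by default** — the
  exposure is the only risk signal unless a spec says otherwise
  (`examples/confounded.yaml` is the labelled non-null preset).
  Covariates are drawn independently of the exposure and of each other;
  real cohorts have correlated covariates (e.g. weight rising across
  ratio tertiles), which the generator does not claim to reproduce.
- **Missingness**: MCAR per-column rates (default: 28.3% lactate, the
  dominant published gap), with an optional MAR hook that tilts the
  missingness log-odds along a named covariate while holding the marginal
  rate. The real cohort's mechanism is uncharacterised; MCAR is the
  default precisely because it is the weakest assumption to simulate
  under. Exposure and outcomes are never made missing (exposure-missing
  patients are an upstream exclusion, not a gap).

Consequently, passing tests demonstrate that the estimators recover the
truth of *this* generative model — hinge-logit risk, independent
covariates, MCAR gaps — at the study's size and event rate. They do not
certify behaviour under covariate-exposure confounding, informative
missingness, or exposure measurement error, none of which the generator
emulates by default.

## Problem sizes and numerical choices

Simulation-based checks use: parameter recovery and turning-point recovery
at n = 20,000 (50 seeds, ±0.3 tolerance ≈ three grid steps); bootstrap
coverage at n = 2,000 with B = 200 over 50 replicates; null LRT calibration
at n = 2,000 over 200 simulations; U-shape argmin recovery of the smooth at
n = 8,000 over 8 seeds (±0.5). These sizes give stable Monte Carlo
verdicts at the cohort's ~6% event rate while keeping the default test run
routine. Ties in the profile likelihood go to the smallest K; tertile ties
go to the lower group; the LRT statistic is clipped at zero within 1e-6
tolerance (beyond which the nesting violation is an error); IRLS tolerance
is 1e-8 on the score, 100-iteration cap; E-value and per-SD transforms are
closed-form. All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); pipeline reruns with the same config are
bit-identical, which the suite asserts.

## Known limitations

- Single knot only: no multi-knot segmented models, no smoothly-joined
  hinge alternatives, and no Davies correction for the searched knot.
- Wald inference throughout; no profile-likelihood or score intervals.
- The bootstrap re-searches K per resample; fixed-K bootstraps (which give
  narrower, anti-conservative intervals) are not offered.
- The generator's covariates are mutually independent and effects enter
  linearly; it is a test harness for the estimators, not a digital twin of
  any ICU population.
- E-values address unmeasured confounding only, and only on the
  risk-ratio scale.
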