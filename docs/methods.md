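# Methods

## Observation model

For plant *i* of line *l*, measured on days t₁ < … < t_m, the model is

y_ij = f(t_j; θ_g(l)) + e_ij,

where *f* is a curve family (expolinear, Gompertz, logistic decay), and
g maps the four lines onto the parameter levels of a grouping scheme.
Within-plant errors are jointly Gaussian with

Cov(e_ij, e_ij′) = σ² · v(t_j) v(t_j′) · ρ^|j−j′|.

Plants are independent, so the likelihood factorizes into per-plant
blocks; plants sharing a day pattern share a covariance block, which is
Cholesky-factorized once per likelihood evaluation.

**AR1 lag metric.** ρ applies per observation-order step. The design is
equally spaced (every other day), so this is equivalent to a
continuous-time AR1 in units of one measurement interval; an unequally
spaced dataset would reinterpret ρ as a per-step correlation, which is
the standard discrete-series convention.

**Variance functions.** `constant`; `exponential`, v(t) = e^{δt} with δ
shared across genotypes; `per_stratum`, one free sd ratio per harvest
day with the first day anchored at 1 for identifiability. Trajectory
traits default to `exponential`; the destructive decay trait (cotyledon
dry weight) defaults to `per_stratum`, and destructive traits use
`independent` correlation — the fitter refuses to estimate ρ when no
plant has more than one observation, since it is structurally
unidentifiable there.

**Curve families.** The expolinear curve is evaluated in log-sum-exp
form, (Cm/Rm)·logaddexp(0, Rm(t−tb)), so exponent arguments up to ±700
never overflow; the Gompertz inner exponent is clipped at 700 (its value
is already 0 to double precision long before that); the decay curve uses
the logistic sigmoid from scipy. The decay family carries a steepness
`rate` fixed at 1 d⁻¹ by default: the three-parameter form (Max, Min,
TT) is what the grouped degrees-of-freedom bookkeeping assumes, and a
`FitControl(free_decay_rate=True)` switch frees it when the steepness is
of interest.

## Estimation

Full maximum likelihood (not REML): information-criterion comparison
across different mean structures requires the full likelihood. σ is
profiled analytically — given the other parameters, σ̂² = (1/n)Σ rᵀV⁻¹r —
leaving a smooth objective over the curve parameters, atanh(ρ), δ (or
log stratum ratios) and log-transformed positive curve parameters
(Cm, Rm, Wf, k, Max−Min, Min), optimized with L-BFGS-B (relative logL
tolerance 1e−8, gradient tolerance 1e−5, max 500 iterations). Starting
values are data-driven: terminal slope/intercept and early log-slope for
expolinear; 1.05×max, the day nearest Wf/e, and a log-log regression
slope for Gompertz; first/last harvest means and the mid-crossing for
decay. If the first start fails to converge, up to 5 seeded perturbed
restarts are tried and the best optimum kept; the `converged` flag
reports the optimizer's verdict honestly.

**Warm-start cascade and nesting.** `fit_schemes` fits UNI first, then
MAPHE/MAHY/GEN3 (each also started from the UNI solution expanded to its
levels), then GEN4 (also started from each coarser solution). Since a
refinement evaluated at a coarsening's optimum reproduces its
likelihood, local optimization from there can only improve it, so the
maximized logL respects the partition order — logL(GEN4) ≥ every
coarser ≥ logL(UNI) — on every dataset. (Published tables of this model
class occasionally violate this ordering, a convergence artifact the
cascade is designed to preclude.)

**Inference.** Standard errors of the curve parameters come from the
inverse of J′Σ̂⁻¹J (J the analytic gradient of the mean function at the
optimum), with the variance parameters held at their estimates — the
conventional GNLS asymptotics, matching the reference R implementation
(`nlme::gnls`), against which the likelihood and coefficients are
cross-checked in the test suite. Wald intervals are estimate ± z·SE. A
singular information matrix raises an error naming the least-informed
parameter. SEs are pure-ML (no finite-sample denominator correction), so
they sit ~2% below the reference implementation's at n ≈ 240; coverage
simulations confirm the 95% intervals cover at nominal rate.

**Degrees of freedom.** k = (levels × curve parameters) + identifiable
nuisance terms: σ, plus ρ when AR1 is estimable, plus δ (exponential) or
S−1 ratios (per-stratum with S harvests). Destructive decay fits on six
harvests therefore report k = 3L + 6. `param_count(scheme, family,
n_variance_terms)` stays generic so any published df convention can be
reproduced by supplying its nuisance count.

## Model selection

AICc with the second-order correction 2k(k+1)/(n−k−1), which is
undefined (and raises) for n ≤ k+1. Support bands: ΔAICc < 2 strong,
[2,4) moderate, [4,10] substantial-to-weak, >10 discard — the unlabeled
gaps in the conventional banding are folded into "moderate" and
"substantial-to-weak" rather than inventing new categories. Evidence
ratios are computed from full-precision deltas; tables recomputed from
*printed* (rounded) logL values can differ in the last digit from
published ones for exactly that reason.

## Synthetic data

The generator produces the design the analysis assumes: four lines × N
plants, days 2,4,…,12 (non-destructive), or independent plants per
harvest (destructive), with exactly the AR1 × variance-function Gaussian
error structure above and the published best-model estimates as default
truth.

* **Noise scale.** σ is anchored so the *marginal* sd on the final day
  equals 10% of the final-day mean averaged across levels (δ = 0.2 d⁻¹
  default shapes the decrease toward earlier days); decay traits anchor
  at 10% of the mean initial plateau, since their final-day mean is near
  zero. The anchor is averaged across levels so the fitted shared-σ
  model is correctly specified. These scales produce standard errors of
  the same order as the published tables at study-like replication
  (~10–14 plants per line).
* **Truncation.** Physical measurements are non-negative, but truncating
  Gaussian draws at zero changes early-day means by tens of percent at
  the default noise scale and would bias exactly the early-phase
  parameters (Rm, tb) the recovery tests certify. Default is therefore
  untruncated draws (negative early-day values can occur);
  `truncate_at_zero=True` enables truncation and reports the count on
  the dataset.
* **What it does not emulate.** Real root measurements have digitization
  error, occasional missing scans, plant mortality, and noise that is
  neither exactly Gaussian nor exactly AR1. Passing recovery tests shows
  the estimator is correct under its assumed model, not that the model
  is correct for any particular experiment.

## Validation problem sizes

The acceptance-style simulations use 200 replicates at 200 plants per
seed-size class for bias (<2%) and coverage (90–99% band) checks, 60
replicates at 14 plants per line for model-selection consistency, and 20
replicates for the mean-recovered-Cm check; each fit takes ~0.1 s, so
the whole suite runs in a couple of minutes. These sizes give Monte
Carlo standard errors several times smaller than the tolerances they
certify.

## End-point traits

One-way fixed-effects F-test, statsmodels Tukey HSD, and an
insert-and-absorb compact letter display: start from one column holding
all groups, split any column containing a significantly different pair,
absorb subset columns, and assign letters in order of descending column
best-mean. Sharing a letter then coincides exactly with pairwise
non-significance for designs of this size. Pooled SEs (√(MSE/n_i)) are
the default, reproducing the identical-SE pattern of balanced published
tables; a per-group option exists for unequal variances (the letters
still come from the pooled Tukey procedure — a documented limitation).

Printed-table comparisons use round-half-up at the printed precision
(23.509 → 24), matching how the published derived statistics were
rounded.

## Known limitations

* No random-effects (mixed-model) trajectories, REML, Bayesian fitting,
  BIC or parameter model-averaging.
* The AR1 block assumes each plant's days are a sorted subsequence of
  the common grid; wildly irregular designs fall back to per-pattern
  blocks but keep the per-step lag convention.
* The pedigree is fixed at two parents + two reciprocal F1s; general
  diallels are out of scope.
* Variance-function covariates other than measurement day (e.g. fitted
  mean) are not implemented.
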