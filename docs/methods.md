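# Methods

## The inferential problem

`metaboclr` analyses nested case-control studies in which each incident case
is matched to one or more controls on attributes such as country, sex, age
and blood-draw date, and the exposure of interest is a panel of correlated
circulating metabolites — here the transsulfuration pathway (PLP,
homocysteine, serine, cystathionine, cysteine) plus folate, SDMA and
neopterin — in relation to renal cell carcinoma risk.

The unit of inference is the matched set. Writing `eta_j = x_j' beta` for
member `j` of a set, the probability that `j` is the case, conditional on
exactly one member being the case, is

```
P(case = j | set) = exp(eta_j) / sum_k exp(eta_k)
```

The conditional log-likelihood is the sum over sets of
`eta_case - logsumexp(eta_members)`, evaluated with log-sum-exp
stabilization. Any column that is constant within every set — in particular
every matching attribute — cancels exactly; this absorption is verified by a
property test and is the reason matching factors are refused as covariates
(sex may act only as an effect modifier, through product terms).

## Standardization

Concentrations are log2 transformed, centered and scaled to unit SD before
entering any model, so all coefficients are log odds ratios per 1 SD of log
concentration. Fitted scales use the n-1 denominator; the fitting population
defaults to all retained subjects, with a controls-only switch. Pearson
correlations between metabolites are computed on log values among controls
only; because correlation is invariant to linear rescaling and to the base
of the logarithm, this equals the correlation of the standardized values.
z-scores are likewise log-base invariant (a change of base is a scale factor
absorbed by the SD), which a property test asserts.

Complete-case handling drops whole sets: a 1:1 set with one incomplete
member contributes nothing to the conditional likelihood, so partial
retention would only break the one-case-per-set invariant without adding
information.

## Priors and posterior computation

Coefficients receive independent Normal(0, 2.5) priors on the standardized
scale — weakly informative at the per-1-SD log-OR magnitudes that occur in
nutritional epidemiology, and enough to keep the posterior proper under
complete separation. The prior scale is configurable and recorded in the run
manifest; the original analysis this design follows used its software's
default weakly-informative priors without stating them, so prior-scale
sensitivity is something a user can probe directly rather than a quantity we
claim to reproduce.

Sampling is Laplace-assisted independence Metropolis. A Newton-Raphson
iteration on the penalized conditional log-likelihood (step-halved, gradient
tolerance 1e-8) finds the posterior mode and observed-information
covariance; each of 4 chains then proposes from a multivariate t with 8
degrees of freedom centered at the mode with the Laplace covariance inflated
by 1.1. For these log-concave, near-Gaussian posteriors the proposal is a
close global approximation, so acceptance rates are high and draws nearly
independent; split R-hat and effective sample size are computed with arviz
and a fit is flagged unconverged when any R-hat exceeds 1.01 (flagged fits
are returned, not discarded). Identical seed and settings give bit-identical
draws. Defaults are 4 chains x 1000 post-warmup draws. The unpenalized
Newton maximizer doubles as a frequentist oracle; a coefficient pushed past
|beta| = 12 is reported as complete separation instead of a spurious finite
estimate.

Point estimates are posterior medians, intervals equal-tailed 90% credible
intervals, both exponentiated to the OR scale and printed to two decimals.

## Model tiers

* minimal: one metabolite + education (4 levels) + fasting status (3 levels)
  — 6 columns;
* additional: minimal + BMI (continuous, per kg/m2) + smoking (3 levels) —
  9 columns;
* mutual: all five metabolites + folate + education + fasting + BMI +
  smoking — 14 columns;
* sensitivity: mutual +SBP / +DBP / +both (blood-pressure-complete sets
  only, dropped whole), +SDMA+neopterin, and folate removed.

Reference levels are the first-listed categories (no/primary education, not
fasting, never smoker). Folate, SDMA and neopterin are standardized like the
metabolites — the transformation statement that motivates this design covers
"metabolite concentrations" generally, and whether folate entered raw or
standardized in the original analysis is not stated; standardized is this
package's choice. BMI and blood pressures enter per unit, mean-centered;
centering is invisible to the conditional likelihood (a within-set constant
shift) but keeps interaction main effects interpretable at the average BMI,
and the centering constant is recorded for the modifier-level contrasts.

## Profiles

A profile assigns each metabolite a value in SD units; the contrast of two
profiles is `exp((w_a - w_b)' beta_met)` per posterior draw of the mutually
adjusted model — covariates cancel by construction. Mid profiles are
all-zero and low = -high, so OR(low vs high) = OR(low vs mid)^2 per draw for
the theoretical sets, and OR(A vs B) x OR(B vs A) = 1 exactly; both are
regression-tested. The theoretical weight tables encode the assumption that
a more abundant cofactor relaxes regulatory restriction of enzyme activity —
substrates down, products up:

| basis | plp | homocysteine | serine | cystathionine | cysteine |
|---|---|---|---|---|---|
| transsulfuration (high) | 1 | -1 | -1 | 0 | 1 |
| cbs (high) | 1 | -1 | -1 | 1 | 0 |
| cse (high) | 1 | 0 | 0 | -1 | 1 |

The empirical basis anchors PLP at +/-1 SD and sets every other metabolite
to its conditional expectation given PLP: the slope of the unadjusted
regression of its standardized log concentration on standardized log PLP
(on standardized variables the slope is the weight in SD units directly).
Slopes are fitted on controls by default — profile construction describes
population covariation, best estimated in the non-diseased sampling frame —
with an all-subjects switch, since the original description does not say
which frame was used.

## Effect modification and ELPD

Interaction models add product terms between one metabolite's z-score and
one modifier at a time (BMI, smoking, sex, SBP, DBP), never jointly. The
per-1-SD OR at modifier value v is `exp(beta_met + gamma (v - c))` for a
continuous modifier centered at c, or `exp(beta_met + gamma_level)` for a
categorical one; at the centering value (or reference level) it equals the
main-effect OR exactly. The default BMI evaluation grid is 20/25/30/35
kg/m2, configurable.

Predictive comparison uses expected log predictive density with the matched
set as the leave-out unit — the conditional likelihood factorizes over sets,
and subjects within a set are not exchangeable. Leave-one-set-out ELPD is
approximated by Pareto-smoothed importance sampling (arviz `psislw`) over
the per-set conditional log-likelihoods; sets with Pareto k > 0.7 are
diagnosed, a fit with more than 10% such sets is flagged, and exact
leave-one-set-out refits are available (and validated against the
approximation within 1 SE on 50-set problems). Comparisons report
`sum(per-set differences)` with `SE = sqrt(n) x SD(differences)`,
interaction model first, so negative means the interaction worsens
out-of-sample fit.

## The synthetic cohort generator

The generator produces the data structure the analysis assumes, with known
truth:

* Analytes are `2**v` with `v` multivariate normal. Means are log2 of the
  control-arm medians; SDs derive from the printed IQRs via the normal-theory
  conversion `SD = (log2 Q3 - log2 Q1) / (2 Phi^-1(0.75))`; the
  homocysteine-cysteine log correlation is 0.44 and all other pairs default
  to an exchangeable 0.2 — a configurable placeholder, since the full
  control-arm correlation matrix is not published. Non-positive-semidefinite
  matrices are rejected with the offending eigenvalue.
* Covariates use the control-arm frequencies (education, fasting, smoking,
  sex, country) and truncated-normal BMI/SBP/DBP/age with IQR-derived SDs.
  Matching attributes are generated set-constant; no caliper machinery is
  simulated.
* One member per set is labeled the case by Gumbel-max sampling of the
  softmax over `eta = x' beta_true`, computed on the generator's theoretical
  standardization scale — exactly the conditional-logistic mechanism, so the
  fitted likelihood is correctly specified and parameter recovery is a clean
  contract: across 100 replicates of 455 sets the 90% intervals cover the
  truth at nominal rate within binomial Monte-Carlo error.
* Blood pressures are masked jointly per subject with probability 0.10
  (missing-completely-at-random), reproducing a realistic ~81% of sets being
  BP-complete; general MCAR masking of other fields is available.

Default `true_beta` is the null vector: the defaults describe the sampled
population, calibrated to the printed control-arm marginals and correlation,
and under the null the control arm is exchangeable with that population, so
calibration round trips (control PLP median 36.4 nmol/L, log correlation
0.44) are exact in expectation. This matters because a nonzero metabolite
effect tilts within-set selection and shifts the *control* marginal away
from the population values (for a PLP log-OR of -0.27, by roughly +7% on the
median) — population calibration and nonnull defaults cannot both hold.
Disease effects are therefore an explicit experimental condition;
`EXAMPLE_TRUE_EFFECTS` supplies a plausible mutually-adjusted effect vector
for recovery studies.

What the generator does not emulate: assay measurement error, storage or
batch artifacts, country-specific recruitment, within-pair correlation of
lifestyle covariates, correlation between SBP and DBP, or any
non-lognormality of the concentration marginals. Passing tests therefore
demonstrate the correctness and calibration of the inferential machinery
under its own assumptions, not robustness to real-data violations of them.

## Numerical choices and degenerate inputs

Log-sum-exp everywhere a set likelihood is formed; Newton convergence at
gradient norm < 1e-8 with step-halving; observed-information covariance;
zero-variance and non-positive concentrations rejected with row
identification; sets without within-set variation in any column raise a
non-identifiability error for the MLE (for single columns they simply
contribute a constant); the degenerate all-zero-SD generator returns exact
medians. Problem sizes in the test suite (455 sets for recovery, 50 sets for
exact-refit ELPD validation, 100 replicates for coverage) are the package's
chosen validation scales.

## Known limitations

The sampler's independence proposal is tuned for the log-concave posteriors
of conditional logistic regression; heavy multimodality (not attainable in
this model class) would defeat it. ELPD importance weights can be unreliable
for highly influential sets — the Pareto-k diagnostic and exact refits are
the mitigation. The generator's exchangeable background correlation is a
placeholder, flagged as such in its docstring; analyses of the real study
would estimate the full matrix from data.
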