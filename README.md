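# metaboclr

Bayesian conditional logistic regression for matched case-control metabolite
panels: per-1-SD odds ratios, joint metabolite-profile contrasts,
effect-modifier contrasts and leave-one-set-out ELPD model comparison, plus a
calibrated synthetic-cohort generator for validating the whole chain against
known truth.

## The problem

In a nested case-control study, each incident case (here: renal cell
carcinoma) is matched to a control on country, sex, age and blood-draw date,
and circulating metabolites of the transsulfuration pathway — PLP (the
active form of vitamin B6), homocysteine, serine, cystathionine and cysteine
— are measured in baseline plasma. The natural likelihood conditions on set
membership: with linear predictors `eta_j = x_j' beta`, member `j` of a set
is the case with probability

```
P(case = j | set) = exp(eta_j) / sum_k exp(eta_k)
```

Matching factors cancel from this likelihood exactly. Concentrations enter
as log2 z-scores, so each coefficient is a log odds ratio per 1 SD of log
concentration; inference is Bayesian (normal priors, posterior sampled by
Laplace-assisted independence Metropolis) with posterior-median ORs and 90%
equal-tailed credible intervals.

Because pathway metabolites vary in concert, the package also estimates
joint profile contrasts: a profile assigns each metabolite a value in SD
units (e.g. "low transsulfuration function" = PLP and cysteine at -1 SD,
homocysteine and serine at +1 SD), and the OR between two profiles is
`exp((w_a - w_b)' beta)` per posterior draw of the mutually adjusted model.
Effect modification (metabolite x BMI, smoking, sex, blood pressure) is
assessed one interaction at a time, with models compared by
leave-one-set-out expected log predictive density (Pareto-smoothed
importance sampling, exact refits for flagged sets).

Individual-level data from studies of this design are typically available
only on request, so the package ships a generator that simulates matched
cohorts with the published control-arm marginals (log-normal, medians and
IQR-derived SDs), the published homocysteine-cysteine log correlation of
0.44, and a conditional-logistic outcome mechanism with known coefficients —
making interval calibration and parameter recovery testable end to end.

## Worked example

```python
import metaboclr as m

cfg = m.GeneratorConfig(n_sets=455, true_beta=m.EXAMPLE_TRUE_EFFECTS, seed=4)
df, truth = m.generate_cohort(cfg)
df, _ = m.filter_complete_sets(df, m.report.REQUIRED_FIELDS)
params = m.fit_standardization(df, m.schema.ANALYTES)

battery, draws = m.run_mutual_model(df, params, seed=5)
for _, row in battery.iterrows():
    print(f"{row['term']:>14}: {row['or']:.2f} ({row['cri_low']:.2f}, {row['cri_high']:.2f})")

ts = m.theoretical_profile_sets()["transsulfuration"]
for r in m.profile_contrast(draws, ts):
    print(ts.basis, r.profile, r.summary)
```

prints (the 14-term mutually adjusted model on a simulated cohort generated
at true ORs 0.76 / 1.10 / 0.90 / 1.12 / 0.81):

```
           plp: 0.72 (0.64, 0.81)
  homocysteine: 0.95 (0.84, 1.09)
        serine: 0.94 (0.82, 1.06)
 cystathionine: 1.02 (0.90, 1.16)
      cysteine: 0.89 (0.78, 1.01)
transsulfuration high 1.00 (1.00, 1.00)
transsulfuration mid 1.39 (1.04, 1.87)
transsulfuration low 1.94 (1.08, 3.50)
```

Each metabolite row is the odds ratio per 1 SD of log concentration with its
90% credible interval — the posterior medians sit within simulation noise of
the generating values. The profile rows give the joint OR of the whole panel
moving from the high-function pattern to mid and low: here the low-function
profile roughly doubles the odds, driven by the protective PLP and cysteine
effects entering the contrast twice (once directly, once via the substrate
terms).

The `examples/` directory holds one narrative script per capability:
simulation and descriptives, single-metabolite batteries, the mutual model
with all four profile bases, BMI interaction with ELPD comparison, and the
end-to-end pipeline (`run_pipeline`, which writes CSV tables, a JSON
manifest with seed/config-hash/convergence, and a run log).

## Data format

Subject tables are plain CSV, one row per participant (see
`metaboclr/schema.py` for columns and category levels): matched-set id,
case indicator, eight analyte concentrations, education/fasting/smoking,
BMI, optional blood pressures, and the set-constant matching attributes.
`read_subject_csv` validates the one-case-per-set rule, key uniqueness and
concentration positivity; empty fields are missing values.

See `docs/methods.md` for the model, priors, sampler, profile and ELPD
details, generator calibration, and known limitations.
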