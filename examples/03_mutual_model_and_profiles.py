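"""Mutually adjusted model and joint metabolite-profile contrasts.

Fits the 14-term mutually adjusted model (all five metabolites + folate +
covariates) and computes the joint odds ratio of moving the whole metabolite
panel between named profiles: the empirical PLP-anchored set and the three
theoretical enzyme-regulation sets (overall transsulfuration, CBS, CSE).
"""

import metaboclr as m

cfg = m.GeneratorConfig(n_sets=455, true_beta=m.EXAMPLE_TRUE_EFFECTS, seed=4)
df, _ = m.generate_cohort(cfg)
df, _ = m.filter_complete_sets(df, m.report.REQUIRED_FIELDS)
params = m.fit_standardization(df, m.schema.ANALYTES)

battery, draws = m.run_mutual_model(df, params, seed=5)
print("mutually adjusted per-1-SD odds ratios:")
for _, row in battery.iterrows():
    print(f"  {row['term']:>14}: {row['or']:.2f} "
          f"({row['cri_low']:.2f}, {row['cri_high']:.2f})")

profile_sets = {"empirical_plp": m.empirical_plp_profiles(df, params)}
profile_sets.update(m.theoretical_profile_sets())
print("\njoint profile contrasts (reference = high):")
for name, pset in profile_sets.items():
    results = m.profile_contrast(draws, pset)
    for r in results:
        tag = " (reference)" if r.profile == r.reference else ""
        print(f"  {name:>16} {r.profile:>4}: {r.summary}{tag}")

print("\nA low-vs-high contrast above 1 means the low-function pattern "
      "(PLP and cysteine down, homocysteine and serine up) carries higher "
      "risk; under the generated protective effects it lands well above 2.")
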