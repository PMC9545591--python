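"""Effect-modifier contrasts and leave-one-set-out ELPD."""

import numpy as np
import pytest

import metaboclr as m


def _degenerate_draws(beta_by_term, centers=None):
    terms = list(beta_by_term)
    arr = np.tile(np.array([beta_by_term[t] for t in terms]), (50, 1))
    return m.PosteriorDraws(
        draws=arr, term_names=terms, n_chains=1, n_draws_per_chain=50, seed=0,
        rhat=np.ones(len(terms)), ess=np.full(len(terms), 50.0),
        meta={"centers": centers or {}},
    )


@pytest.fixture(scope="module")
def interaction_cohort():
    """Cohort generated with a real cysteine x BMI interaction."""
    cfg = m.GeneratorConfig(
        n_sets=455,
        true_beta=dict(m.EXAMPLE_TRUE_EFFECTS),
        interaction_gamma={("cysteine", "bmi"): -0.06},
        seed=31,
    )
    df, truth = m.generate_cohort(cfg)
    df, _ = m.filter_complete_sets(df, m.report.REQUIRED_FIELDS)
    params = m.fit_standardization(df, m.schema.ANALYTES)
    return df, params, truth


def test_continuous_contrast_closed_form():
    draws = _degenerate_draws(
        {"cysteine": -0.2, "cysteine:bmi": -0.05}, centers={"bmi": 26.0}
    )
    s = m.contrast_at_modifier_level(draws, "cysteine", "bmi", 35.0)
    assert s.or_estimate == pytest.approx(np.exp(-0.2 - 0.05 * 9.0), rel=1e-12)


def test_zero_gamma_gives_constant_or_across_levels():
    draws = _degenerate_draws(
        {"plp": -0.3, "plp:bmi": 0.0}, centers={"bmi": 26.0}
    )
    ors = [
        m.contrast_at_modifier_level(draws, "plp", "bmi", v).or_estimate
        for v in (20.0, 25.0, 30.0, 35.0)
    ]
    assert np.allclose(ors, ors[0])


def test_contrast_at_centering_value_equals_main_effect():
    draws = _degenerate_draws(
        {"serine": -0.11, "serine:bmi": 0.07}, centers={"bmi": 26.5}
    )
    s = m.contrast_at_modifier_level(draws, "serine", "bmi", 26.5)
    assert s.or_estimate == pytest.approx(np.exp(-0.11), rel=1e-12)


def test_categorical_contrast_and_unknown_level():
    draws = _degenerate_draws(
        {"plp": -0.2, "plp:smoking[former]": 0.1, "plp:smoking[current]": -0.3}
    )
    never = m.contrast_at_modifier_level(draws, "plp", "smoking", "never")
    current = m.contrast_at_modifier_level(draws, "plp", "smoking", "current")
    assert never.or_estimate == pytest.approx(np.exp(-0.2), rel=1e-12)
    assert current.or_estimate == pytest.approx(np.exp(-0.5), rel=1e-12)
    with pytest.raises(KeyError):
        m.contrast_at_modifier_level(draws, "plp", "smoking", "cigars")


def test_smoking_interaction_adds_two_columns(interaction_cohort):
    df, params, _ = interaction_cohort
    spec = m.interaction_spec("plp", "smoking")
    d = m.build_design(df, spec, params)
    extra = [c for c in d.columns if c.startswith("plp:smoking")]
    assert extra == ["plp:smoking[former]", "plp:smoking[current]"]
    assert d.n_terms == 16


def test_sex_modifier_allowed_only_as_interaction(interaction_cohort):
    df, params, _ = interaction_cohort
    spec = m.interaction_spec("plp", "sex")
    d = m.build_design(df, spec, params)
    assert "plp:sex[female]" in d.columns
    assert "sex[female]" not in d.columns  # main effect absorbed by matching
    bad = m.ModelSpec(metabolites=("plp",), covariates=("fasting",),
                      interaction=("plp", "age"))
    with pytest.raises(ValueError, match="matching factor"):
        m.build_design(df, bad, params)


def test_interaction_recovery(interaction_cohort):
    df, params, truth = interaction_cohort
    draws, design = m.fit_interaction_model(
        df, params, "cysteine", "bmi", seed=5, n_draws=800, n_chains=2, warmup=150
    )
    gamma = draws.col("cysteine:bmi")
    assert np.median(gamma) == pytest.approx(-0.06, abs=0.045)
    s35 = m.contrast_at_modifier_level(draws, "cysteine", "bmi", 35.0)
    s20 = m.contrast_at_modifier_level(draws, "cysteine", "bmi", 20.0)
    assert s35.or_estimate < s20.or_estimate  # stronger inverse at high BMI


def test_elpd_self_comparison_is_exactly_zero(interaction_cohort):
    df, params, _ = interaction_cohort
    _, draws = m.run_mutual_model(
        df, params, seed=6, n_draws=400, n_chains=2, warmup=100
    )
    design = m.build_design(df, m.mutual_spec(), params)
    e = m.elpd_loo(draws, design)
    comp = m.elpd_compare(e, e)
    assert comp.elpd_diff == 0.0
    assert comp.se_diff == 0.0
    assert comp.n_sets == design.n_sets
    assert np.all(np.isfinite(e.per_set))
    assert e.total == pytest.approx(e.per_set.sum())


def test_elpd_matches_exact_refits_within_one_se():
    """PSIS approximation vs brute-force leave-one-set-out refits, 50 sets."""
    cfg = m.GeneratorConfig(n_sets=50, true_beta={"plp": -0.4}, seed=41)
    df, _ = m.generate_cohort(cfg)
    df, _ = m.filter_complete_sets(df, m.report.REQUIRED_FIELDS)
    params = m.fit_standardization(df, m.schema.ANALYTES)
    spec = m.ModelSpec(metabolites=("plp", "cysteine"), label="small")
    design = m.build_design(df, spec, params)
    draws = m.sample_posterior(design, n_draws=1500, n_chains=2, seed=42, warmup=150)
    approx = m.elpd_loo(draws, design)
    exact = m.elpd_exact_refit(
        design, seed=43, n_draws=800, n_chains=2, warmup=150
    )
    diff = approx.per_set - exact
    se = np.sqrt(len(diff)) * np.std(diff, ddof=1)
    assert abs(diff.sum()) <= max(se, 0.1)
    assert not approx.flagged


def test_interaction_penalized_without_true_interaction(null_cohort):
    """Extra parameters cannot improve out-of-sample fit in expectation."""
    df, _ = null_cohort
    df, _ = m.filter_complete_sets(df, m.report.REQUIRED_FIELDS)
    params = m.fit_standardization(df, m.schema.ANALYTES)
    base_design = m.build_design(df, m.mutual_spec(), params)
    base_draws = m.sample_posterior(base_design, n_draws=600, n_chains=2, seed=7, warmup=100)
    base = m.elpd_loo(base_draws, base_design)
    diffs = []
    for k, met in enumerate(("plp", "cysteine", "homocysteine")):
        draws, design = m.fit_interaction_model(
            df, params, met, "bmi", seed=8 + k, n_draws=600, n_chains=2, warmup=100
        )
        comp = m.elpd_compare(m.elpd_loo(draws, design), base)
        diffs.append(comp.elpd_diff)
        # sign convention: interaction model listed first
        assert comp.n_sets == base.n_sets
    assert np.mean(diffs) <= 1.0  # on average no predictive gain


def test_elpd_requires_matching_sets(interaction_cohort):
    df, params, _ = interaction_cohort
    design = m.build_design(df, m.mutual_spec(), params)
    draws = m.sample_posterior(design, n_draws=200, n_chains=2, seed=9, warmup=50)
    e = m.elpd_loo(draws, design)
    half = m.ElpdResult(
        per_set=e.per_set[:10], pareto_k=e.pareto_k[:10], set_labels=e.set_labels[:10]
    )
    with pytest.raises(ValueError, match="same sets"):
        m.elpd_compare(e, half)
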