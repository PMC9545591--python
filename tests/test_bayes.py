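"""Conditional likelihood, Newton MLE, posterior sampler, OR summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize
from scipy.special import expit

import metaboclr as m
from metaboclr.bayes import NonIdentifiableError, set_log_probabilities

from conftest import random_sets_design, toy_pairs_design


def test_null_beta_loglik_is_uniform_within_sets():
    d = toy_pairs_design(np.linspace(-1, 1, 7))
    ll = m.conditional_loglik(np.zeros(1), d)
    assert ll == pytest.approx(-7 * np.log(2.0), abs=1e-12)


def test_single_pair_closed_form():
    d = toy_pairs_design([1.0])  # case z=1, control z=0
    ll = m.conditional_loglik(np.array([np.log(2.0)]), d)
    assert ll == pytest.approx(np.log(2.0 / 3.0), abs=1e-12)


def test_dimension_mismatch_rejected():
    d = toy_pairs_design([1.0])
    with pytest.raises(ValueError, match="terms"):
        m.conditional_loglik(np.zeros(2), d)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.integers(0, 10_000), st.floats(-3, 3, allow_nan=False))
def test_set_constant_columns_never_change_likelihood(seed, coef):
    """Matching-factor absorption: set-constant columns cancel exactly."""
    rng = np.random.default_rng(seed)
    d = random_sets_design(rng, n_sets=12)
    beta = rng.normal(size=d.n_terms)
    base = m.conditional_loglik(beta, d)
    const = np.repeat(rng.normal(size=d.n_sets), d.sizes)[:, None]
    d2 = m.make_design(
        np.hstack([d.X, const]),
        d.columns + ["setconst"],
        np.repeat(d.set_labels, d.sizes),
        _case_indicator(d),
    )
    aug = m.conditional_loglik(np.append(beta, coef), d2)
    assert aug == pytest.approx(base, abs=1e-10)


def _case_indicator(d):
    y = np.zeros(d.X.shape[0], dtype=bool)
    y[d.case_rows] = True
    return y


def test_set_probabilities_match_brute_force_enumeration():
    """Sets of size <= 4: direct softmax enumeration to 1e-12."""
    rng = np.random.default_rng(42)
    for trial in range(20):
        d = random_sets_design(rng, n_sets=15, max_size=4, n_terms=3)
        beta = rng.normal(scale=1.5, size=3)
        logp = set_log_probabilities(beta, d)
        for s in range(d.n_sets):
            rows = np.flatnonzero(d.row_block == s)
            eta = d.X[rows] @ beta
            probs = np.exp(eta) / np.exp(eta).sum()
            case_local = np.where(rows == d.case_rows[s])[0][0]
            assert np.exp(logp[s]) == pytest.approx(probs[case_local], abs=1e-12)


def _difference_logistic_mle(d):
    """Independent 1:1 oracle: BFGS on the pair-difference logistic loglik."""
    ctrl_rows = []
    for s in range(d.n_sets):
        rows = np.flatnonzero(d.row_block == s)
        ctrl_rows.append([r for r in rows if r != d.case_rows[s]][0])
    diffs = d.X[d.case_rows] - d.X[ctrl_rows]

    def nll(b):
        return -np.sum(np.log(expit(diffs @ b)))

    res = optimize.minimize(nll, np.zeros(d.n_terms), method="BFGS")
    return res.x


def test_mle_equals_difference_logistic_on_pairs():
    rng = np.random.default_rng(3)
    n = 200
    X = rng.normal(size=(2 * n, 2))
    set_ids = np.repeat(np.arange(n), 2)
    eta = X @ np.array([0.8, -0.4])
    is_case = np.zeros(2 * n, dtype=bool)
    for s in range(n):
        rows = [2 * s, 2 * s + 1]
        p = expit(eta[rows[0]] - eta[rows[1]])
        is_case[rows[0] if rng.random() < p else rows[1]] = True
    d = m.make_design(X, ["x1", "x2"], set_ids, is_case)
    fit = m.conditional_mle(d)
    assert fit.converged and not fit.separated
    oracle = _difference_logistic_mle(d)
    assert np.allclose(fit.beta, oracle, atol=1e-6)


def test_mle_matches_statsmodels_conditional_logit():
    """Independent implementation check on 1:2 matched sets."""
    sm = pytest.importorskip("statsmodels.api")
    from statsmodels.discrete.conditional_models import ConditionalLogit

    rng = np.random.default_rng(4)
    d = random_sets_design(rng, n_sets=120, max_size=3, n_terms=2)
    fit = m.conditional_mle(d)
    y = _case_indicator(d).astype(float)
    ref = ConditionalLogit(y, d.X, groups=np.repeat(np.arange(d.n_sets), d.sizes)).fit(
        disp=0
    )
    assert np.allclose(fit.beta, ref.params, atol=1e-5)


def test_mle_recovers_simulated_coefficient():
    rng = np.random.default_rng(5)
    n = 500
    X = rng.normal(size=(2 * n, 1))
    eta = 0.5 * X[:, 0]
    is_case = np.zeros(2 * n, dtype=bool)
    for s in range(n):
        p = expit(eta[2 * s] - eta[2 * s + 1])
        is_case[2 * s if rng.random() < p else 2 * s + 1] = True
    d = m.make_design(X, ["x"], np.repeat(np.arange(n), 2), is_case)
    fit = m.conditional_mle(d)
    assert fit.beta[0] == pytest.approx(0.5, abs=0.15)


def test_separation_flagged():
    d = toy_pairs_design(np.ones(20))  # every within-pair difference positive
    with pytest.warns(UserWarning, match="separation"):
        fit = m.conditional_mle(d)
    assert fit.separated and not fit.converged


def test_uninformative_design_rejected():
    X = np.ones((6, 1))
    d = m.make_design(
        X, ["c"], np.repeat([0, 1, 2], 2), np.tile([True, False], 3)
    )
    assert d.set_constant_columns() == ["c"]
    with pytest.raises(NonIdentifiableError):
        m.conditional_mle(d)


def test_posterior_matches_laplace_at_moderate_n():
    rng = np.random.default_rng(6)
    n = 455
    X = rng.normal(size=(2 * n, 1))
    eta = -0.3 * X[:, 0]
    is_case = np.zeros(2 * n, dtype=bool)
    for s in range(n):
        p = expit(eta[2 * s] - eta[2 * s + 1])
        is_case[2 * s if rng.random() < p else 2 * s + 1] = True
    d = m.make_design(X, ["x"], np.repeat(np.arange(n), 2), is_case)
    mode, cov = m.laplace_approximation(d)
    draws = m.sample_posterior(d, n_draws=2000, n_chains=4, seed=7, warmup=100)
    assert draws.converged
    assert draws.col("x").mean() == pytest.approx(mode[0], abs=0.02)
    assert draws.col("x").std() == pytest.approx(np.sqrt(cov[0, 0]), rel=0.20)


def test_tight_prior_dominates():
    d = toy_pairs_design(np.linspace(-1, 1, 30))
    draws = m.sample_posterior(
        d, prior=m.PriorSpec(scale=1e-4), n_draws=500, n_chains=2, seed=8, warmup=100
    )
    assert draws.col("z").std() < 1e-3
    assert abs(draws.col("z").mean()) < 1e-3


def test_separated_data_proper_posterior_with_default_prior():
    d = toy_pairs_design(np.ones(20))
    draws = m.sample_posterior(d, n_draws=500, n_chains=2, seed=9, warmup=100)
    assert np.all(np.isfinite(draws.draws))


def test_sampler_bit_identical_under_seed():
    d = toy_pairs_design(np.linspace(-1, 1, 20))
    a = m.sample_posterior(d, n_draws=200, n_chains=2, seed=10, warmup=50)
    b = m.sample_posterior(d, n_draws=200, n_chains=2, seed=10, warmup=50)
    assert np.array_equal(a.draws, b.draws)
    c = m.sample_posterior(d, n_draws=200, n_chains=2, seed=11, warmup=50)
    assert not np.array_equal(a.draws, c.draws)


def test_summarize_or_degenerate_draws():
    d = toy_pairs_design([1.0])
    draws = m.PosteriorDraws(
        draws=np.zeros((100, 1)), term_names=["z"], n_chains=1,
        n_draws_per_chain=100, seed=0, rhat=np.array([1.0]), ess=np.array([100.0]),
    )
    s = m.summarize_or(draws, "z")
    assert (s.or_estimate, s.cri_low, s.cri_high) == (1.0, 1.0, 1.0)
    assert str(s) == "1.00 (1.00, 1.00)"


def test_summarize_or_normal_quantile_oracle():
    rng = np.random.default_rng(12)
    mu, sd = -0.2744, 0.08
    arr = rng.normal(mu, sd, size=(10**6, 1))
    draws = m.PosteriorDraws(
        draws=arr, term_names=["plp"], n_chains=1, n_draws_per_chain=10**6,
        seed=0, rhat=np.array([1.0]), ess=np.array([1e6]),
    )
    s = m.summarize_or(draws, "plp", level=0.90)
    z = 1.6448536269514722
    assert s.or_estimate == pytest.approx(np.exp(mu), rel=1e-3)
    assert s.cri_low == pytest.approx(np.exp(mu - z * sd), rel=2e-3)
    assert s.cri_high == pytest.approx(np.exp(mu + z * sd), rel=2e-3)
    assert f"{s}" == f"{s.or_estimate:.2f} ({s.cri_low:.2f}, {s.cri_high:.2f})"


def test_summarize_or_rejects_bad_level():
    d = toy_pairs_design([1.0])
    draws = m.sample_posterior(d, n_draws=100, n_chains=2, seed=1, warmup=50)
    with pytest.raises(ValueError, match="level"):
        m.summarize_or(draws, "z", level=1.5)
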