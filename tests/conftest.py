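import warnings

import numpy as np
import pandas as pd
import pytest

import metaboclr as m

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def null_cohort():
    """120 1:1 sets with no metabolite-outcome association."""
    cfg = m.GeneratorConfig(n_sets=120, seed=11)
    df, truth = m.generate_cohort(cfg)
    return df, truth


@pytest.fixture(scope="session")
def effect_cohort():
    """455 1:1 sets generated at the example effect vector."""
    cfg = m.GeneratorConfig(n_sets=455, true_beta=m.EXAMPLE_TRUE_EFFECTS, seed=23)
    df, truth = m.generate_cohort(cfg)
    return df, truth


@pytest.fixture(scope="session")
def effect_fit(effect_cohort):
    """Mutually adjusted posterior on the effect cohort (shared across tests)."""
    df, truth = effect_cohort
    df, _ = m.filter_complete_sets(df, m.report.REQUIRED_FIELDS)
    params = m.fit_standardization(df, m.schema.ANALYTES)
    battery, draws = m.run_mutual_model(
        df, params, seed=3, n_draws=1000, n_chains=4, warmup=200
    )
    return df, params, battery, draws


def toy_pairs_design(diffs, seed=0):
    """1:1 sets with one column; case z = diff, control z = 0."""
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    X = np.zeros((2 * n, 1))
    X[::2, 0] = diffs
    set_ids = np.repeat(np.arange(n), 2)
    is_case = np.tile([True, False], n)
    return m.make_design(X, ["z"], set_ids, is_case)


def random_sets_design(rng, n_sets=30, max_size=4, n_terms=3):
    """Random designs with variable set sizes (2..max_size)."""
    rows, sets, cases = [], [], []
    for s in range(n_sets):
        size = int(rng.integers(2, max_size + 1))
        case_idx = int(rng.integers(size))
        for j in range(size):
            rows.append(rng.normal(size=n_terms))
            sets.append(s)
            cases.append(j == case_idx)
    X = np.asarray(rows)
    return m.make_design(X, [f"x{j}" for j in range(n_terms)], np.array(sets), cases)
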