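"""Profile weight tables and joint OR contrasts."""

import numpy as np
import pandas as pd
import pytest

import metaboclr as m
from metaboclr.profiles import PROFILE_LABELS


def _degenerate_draws(beta_by_term):
    terms = list(beta_by_term)
    arr = np.tile(np.array([beta_by_term[t] for t in terms]), (50, 1))
    return m.PosteriorDraws(
        draws=arr, term_names=terms, n_chains=1, n_draws_per_chain=50,
        seed=0, rhat=np.ones(len(terms)), ess=np.full(len(terms), 50.0),
    )


MUTUAL_POINT_ORS = {
    "plp": 0.76, "homocysteine": 1.10, "serine": 0.90,
    "cystathionine": 1.12, "cysteine": 0.81,
}


def test_theoretical_weight_tables_cell_for_cell():
    sets = m.theoretical_profile_sets()
    ts = sets["transsulfuration"]
    assert [ts["high"].weights[k] for k in m.schema.METABOLITES] == [1, -1, -1, 0, 1]
    assert [ts["low"].weights[k] for k in m.schema.METABOLITES] == [-1, 1, 1, 0, -1]
    cbs = sets["cbs"]
    assert [cbs["high"].weights[k] for k in m.schema.METABOLITES] == [1, -1, -1, 1, 0]
    cse = sets["cse"]
    assert [cse["high"].weights[k] for k in m.schema.METABOLITES] == [1, 0, 0, -1, 1]
    for ps in sets.values():
        assert all(w == 0 for w in ps["mid"].weights.values())
        for k in m.schema.METABOLITES:
            assert ps["high"].weights[k] == -ps["low"].weights[k]


def test_empirical_profile_toy_slope():
    """5 controls with a hand-computable standardized slope."""
    zp = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    zh = 0.4 * zp  # exact slope 0.4, zero residual
    params = m.StandardizationParams(
        mean_log2={a: 0.0 for a in m.schema.ANALYTES},
        sd_log2={a: 1.0 for a in m.schema.ANALYTES},
    )
    df = pd.DataFrame({a: 2.0 ** np.zeros(5) for a in m.schema.ANALYTES})
    df["plp"] = 2.0**zp
    df["homocysteine"] = 2.0**zh
    df["serine"] = 2.0 ** (0.0 * zp + 0.01 * np.array([1, -1, 0, 1, -1]))
    df["is_case"] = False
    df["set_id"] = range(5)
    ps = m.empirical_plp_profiles(df, params)
    assert ps["high"].weights["plp"] == 1.0
    assert ps["high"].weights["homocysteine"] == pytest.approx(0.4, abs=1e-12)
    assert ps["low"].weights["homocysteine"] == pytest.approx(-0.4, abs=1e-12)
    # cystathionine/cysteine constant-in-z -> slope 0
    assert ps["high"].weights["cysteine"] == pytest.approx(0.0, abs=1e-12)


def test_empirical_profiles_need_plp_variance():
    params = m.StandardizationParams(
        mean_log2={a: 0.0 for a in m.schema.ANALYTES},
        sd_log2={a: 1.0 for a in m.schema.ANALYTES},
    )
    df = pd.DataFrame({a: np.ones(5) for a in m.schema.ANALYTES})
    df["is_case"] = False
    with pytest.raises(ValueError, match="PLP"):
        m.empirical_plp_profiles(df, params)


def test_low_vs_high_transsulfuration_closed_form():
    """Degenerate posterior at the mutually adjusted point ORs -> ~2.59."""
    draws = _degenerate_draws({k: np.log(v) for k, v in MUTUAL_POINT_ORS.items()})
    ts = m.theoretical_profile_sets()["transsulfuration"]
    res = {r.profile: r for r in m.profile_contrast(draws, ts, reference="high")}
    expected = np.exp(
        -2 * np.log(0.76) + 2 * np.log(1.10) + 2 * np.log(0.90) - 2 * np.log(0.81)
    )
    assert expected == pytest.approx(2.59, abs=0.01)
    assert res["low"].summary.or_estimate == pytest.approx(expected, rel=1e-12)
    assert res["high"].summary.or_estimate == 1.0


def test_contrast_identities_per_draw(effect_fit):
    _, _, _, draws = effect_fit
    ts = m.theoretical_profile_sets()["cse"]
    w_high = np.array([ts["high"].weights[k] for k in m.schema.METABOLITES])
    bmet = draws.draws[:, :5]
    lo_lh = bmet @ (-2 * w_high)  # low vs high
    lo_lm = bmet @ (-1 * w_high)  # low vs mid
    lo_hl = bmet @ (2 * w_high)  # high vs low
    # antisymmetry: OR(A vs B) * OR(B vs A) = 1 exactly, per draw
    assert np.allclose(lo_lh + lo_hl, 0.0, atol=1e-12)
    # additivity / high-low symmetry: log-OR(low vs high) = 2 log-OR(low vs mid)
    assert np.allclose(lo_lh, 2 * lo_lm, atol=1e-12)


def test_profile_vs_itself_is_unity(effect_fit):
    _, _, _, draws = effect_fit
    ts = m.theoretical_profile_sets()["transsulfuration"]
    res = m.profile_contrast(draws, ts, reference="high")
    ref = [r for r in res if r.profile == "high"][0]
    assert (ref.summary.or_estimate, ref.summary.cri_low, ref.summary.cri_high) == (
        1.0, 1.0, 1.0,
    )


def test_contrast_multiplicativity_across_references(effect_fit):
    """OR(low vs high) = OR(low vs mid) x OR(mid vs high) per draw."""
    _, _, _, draws = effect_fit
    ts = m.theoretical_profile_sets()["transsulfuration"]
    w = {l: np.array([ts[l].weights[k] for k in m.schema.METABOLITES]) for l in PROFILE_LABELS}
    bmet = draws.draws[:, :5]
    lh = bmet @ (w["low"] - w["high"])
    lm = bmet @ (w["low"] - w["mid"])
    mh = bmet @ (w["mid"] - w["high"])
    assert np.allclose(np.exp(lh), np.exp(lm) * np.exp(mh), rtol=1e-12)


def test_contrast_table_marks_reference(effect_fit):
    df, params, _, draws = effect_fit
    ps = m.empirical_plp_profiles(df, params)
    table = m.contrast_table(m.profile_contrast(draws, ps))
    assert set(table["profile"]) == set(PROFILE_LABELS)
    assert table.loc[table["profile"] == "high", "is_reference"].all()
    # generated protective PLP: low profile confers higher risk
    low_or = float(table.loc[table["profile"] == "low", "or"].iloc[0])
    assert low_or > 1.0


def test_missing_metabolite_term_rejected():
    draws = _degenerate_draws({"plp": 0.0})
    ts = m.theoretical_profile_sets()["cbs"]
    with pytest.raises(KeyError, match="metabolite"):
        m.profile_contrast(draws, ts)
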