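"""Joint metabolite profiles and their odds-ratio contrasts.

Because metabolites of one pathway vary in concert, single-coefficient odds
ratios answer a counterfactual ("this metabolite up, everything else held
fixed") that never occurs physiologically.  A profile is instead a named
vector of metabolite values in SD units; the contrast of two profiles is the
joint odds ratio of moving the whole panel from one pattern to the other,
computed per posterior draw of the mutually adjusted model as
``exp((w_a - w_b) . beta_metabolites)``.

Four profile bases are provided:

* ``empirical_plp`` — PLP set to +1/0/-1 SD, the other metabolites at their
  conditional expectations given PLP (slopes of unadjusted regressions of
  each standardized log concentration on standardized log PLP);
* ``transsulfuration`` — regulatory control of the whole pathway: cofactor
  (PLP) and product (cysteine) up means substrates (homocysteine, serine)
  down; cystathionine, an intermediate, held at its mean;
* ``cbs`` — control of cystathionine beta-synthase: PLP and cystathionine
  (its product) up, homocysteine and serine (its substrates) down;
* ``cse`` — control of cystathionine gamma-lyase: PLP and cysteine up,
  cystathionine (its substrate) down.

Every basis has three profiles (high, mid, low): mid is the all-mean profile
and low is the elementwise negation of high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import OrSummary, PosteriorDraws, summarize_or
from .preprocess import StandardizationParams, apply_standardization
from .schema import METABOLITES

PROFILE_LABELS = ("high", "mid", "low")


@dataclass
class ProfileDefinition:
    """Per-metabolite weights in SD units for one named profile."""

    label: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if self.label not in PROFILE_LABELS:
            raise ValueError(f"profile label must be one of {PROFILE_LABELS}")
        if set(self.weights) != set(METABOLITES):
            raise ValueError("profile weights must cover exactly the five metabolites")

    def vector(self) -> np.ndarray:
        return np.array([self.weights[m] for m in METABOLITES])


@dataclass
class ProfileSet:
    """Three profiles (high/mid/low) on one basis of comparison."""

    basis: str
    profiles: dict[str, ProfileDefinition]

    def __post_init__(self) -> None:
        if set(self.profiles) != set(PROFILE_LABELS):
            raise ValueError("a profile set needs exactly high, mid and low")
        mid = self.profiles["mid"].vector()
        if not np.allclose(mid, 0.0):
            raise ValueError("mid profile must set every metabolite to its mean")
        if not np.allclose(
            self.profiles["high"].vector(), -self.profiles["low"].vector()
        ):
            raise ValueError("high and low profiles must be elementwise opposites")

    def __getitem__(self, label: str) -> ProfileDefinition:
        return self.profiles[label]


@dataclass
class ContrastResult:
    profile: str
    reference: str
    summary: OrSummary


def _make_set(basis: str, high: dict[str, float]) -> ProfileSet:
    return ProfileSet(
        basis=basis,
        profiles={
            "high": ProfileDefinition("high", dict(high)),
            "mid": ProfileDefinition("mid", {m: 0.0 for m in METABOLITES}),
            "low": ProfileDefinition("low", {m: -w for m, w in high.items()}),
        },
    )


def theoretical_profile_sets() -> dict[str, ProfileSet]:
    """The three enzyme-regulation profile bases (fixed weight tables)."""
    return {
        "transsulfuration": _make_set(
            "transsulfuration",
            {"plp": 1.0, "homocysteine": -1.0, "serine": -1.0,
             "cystathionine": 0.0, "cysteine": 1.0},
        ),
        "cbs": _make_set(
            "cbs",
            {"plp": 1.0, "homocysteine": -1.0, "serine": -1.0,
             "cystathionine": 1.0, "cysteine": 0.0},
        ),
        "cse": _make_set(
            "cse",
            {"plp": 1.0, "homocysteine": 0.0, "serine": 0.0,
             "cystathionine": -1.0, "cysteine": 1.0},
        ),
    }


def empirical_plp_profiles(
    df: pd.DataFrame,
    params: StandardizationParams,
    population: str = "controls",
) -> ProfileSet:
    """PLP-anchored empirical profiles.

    PLP is set to +1/0/-1 SD for high/mid/low; every other metabolite is set
    to its conditional expectation given PLP, i.e. the slope of the simple
    linear regression of its standardized log concentration on standardized
    log PLP (on standardized variables that slope equals the weight in SD
    units directly).  Slopes are fitted on controls by default
    (``population="all"`` uses everyone).
    """
    if population == "controls":
        sub = df.loc[~df["is_case"].astype(bool)]
    elif population == "all":
        sub = df
    else:
        raise ValueError("population must be 'controls' or 'all'")
    if len(sub) < 3:
        raise ValueError("need at least 3 subjects to fit profile slopes")
    z = apply_standardization(sub, list(METABOLITES), params)
    zp = z["plp"].to_numpy()
    var = float(np.var(zp))
    if var == 0:
        raise ValueError("degenerate PLP variance; cannot anchor profiles")
    high = {"plp": 1.0}
    for m in METABOLITES:
        if m != "plp":
            zm = z[m].to_numpy()
            high[m] = float(np.cov(zm, zp, ddof=0)[0, 1] / var)
    return _make_set("empirical_plp", high)


def profile_contrast(
    draws: PosteriorDraws,
    profile_set: ProfileSet,
    reference: str = "high",
    level: float = 0.90,
) -> list[ContrastResult]:
    """Joint OR of each profile against the reference profile.

    Per draw, log-OR(profile vs reference) = (w_profile - w_reference) dotted
    with the five metabolite coefficients; everything else in the model
    cancels.  The reference row is emitted with a degenerate OR of 1.
    """
    missing = [m for m in METABOLITES if m not in draws.term_names]
    if missing:
        raise KeyError(f"posterior lacks metabolite terms: {missing}")
    if reference not in PROFILE_LABELS:
        raise ValueError(f"reference must be one of {PROFILE_LABELS}")
    out = []
    w_ref = profile_set[reference].weights
    for label in PROFILE_LABELS:
        if label == reference:
            summary = OrSummary(
                name=f"{profile_set.basis}:{label}",
                or_estimate=1.0, cri_low=1.0, cri_high=1.0, level=level,
            )
        else:
            contrast = {
                m: profile_set[label].weights[m] - w_ref[m] for m in METABOLITES
            }
            summary = summarize_or(
                draws, contrast, level=level, name=f"{profile_set.basis}:{label}"
            )
        out.append(ContrastResult(profile=label, reference=reference, summary=summary))
    return out


def contrast_table(results: list[ContrastResult]) -> pd.DataFrame:
    """Tidy table of profile contrasts, reference rows marked."""
    rows = []
    for r in results:
        basis, label = r.summary.name.split(":", 1)
        rows.append(
            {
                "basis": basis,
                "profile": label,
                "or": r.summary.or_estimate,
                "cri_low": r.summary.cri_low,
                "cri_high": r.summary.cri_high,
                "is_reference": label == r.reference,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "ContrastResult",
    "PROFILE_LABELS",
    "ProfileDefinition",
    "ProfileSet",
    "contrast_table",
    "empirical_plp_profiles",
    "profile_contrast",
    "theoretical_profile_sets",
]
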