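"""Design construction and the standard battery of risk models.

Model tiers mirror the analysis plan of a matched metabolomics case-control
study:

* minimally adjusted — one metabolite plus education and fasting status;
* additionally adjusted — minimal plus BMI (continuous) and smoking status;
* mutually adjusted — all five transsulfuration metabolites jointly, plus
  folate, education, fasting, BMI and smoking;
* sensitivity variants — blood-pressure adjustment on the BP-complete subset,
  kidney-function/immune-activation markers (SDMA, neopterin), and removal of
  folate.

Matching factors never enter the design; the conditional likelihood absorbs
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import schema
from .bayes import (
    DesignMatrix,
    PosteriorDraws,
    PriorSpec,
    make_design,
    sample_posterior,
    summarize_or,
)
from .preprocess import StandardizationParams, apply_standardization

#: Continuous covariates entered on their natural (per-unit) scale.
_NATURAL_SCALE = ("bmi", "sbp", "dbp")


@dataclass
class ModelSpec:
    """Declarative description of one conditional-logistic model.

    ``covariates`` may contain categorical names (expanded to dummies against
    the declared reference level), the analyte covariates (standardized like
    the metabolites) and the natural-scale continuous covariates.
    ``interaction`` adds product terms between one metabolite's z-score and
    one modifier.  ``subset`` currently supports ``"bp_complete"``: keep only
    sets in which every member has both blood pressures measured.
    """

    metabolites: tuple[str, ...]
    covariates: tuple[str, ...] = ()
    interaction: tuple[str, str] | None = None
    subset: str | None = None
    prior: PriorSpec = field(default_factory=PriorSpec)
    label: str = "model"

    def __post_init__(self) -> None:
        if not self.metabolites:
            raise ValueError("metabolite models need at least one metabolite term")
        unknown = set(self.metabolites) - set(schema.METABOLITES)
        if unknown:
            raise ValueError(f"unknown metabolites: {sorted(unknown)}")


def minimal_spec(metabolite: str, **kw) -> ModelSpec:
    return ModelSpec(
        metabolites=(metabolite,),
        covariates=("education", "fasting"),
        label=f"minimal[{metabolite}]",
        **kw,
    )


def additional_spec(metabolite: str, **kw) -> ModelSpec:
    return ModelSpec(
        metabolites=(metabolite,),
        covariates=("education", "fasting", "bmi", "smoking"),
        label=f"additional[{metabolite}]",
        **kw,
    )


def mutual_spec(**kw) -> ModelSpec:
    """All five metabolites jointly, folate-adjusted: the 14-column design."""
    return ModelSpec(
        metabolites=schema.METABOLITES,
        covariates=("folate", "education", "fasting", "bmi", "smoking"),
        label="mutual",
        **kw,
    )


def bp_complete_sets(df: pd.DataFrame) -> pd.DataFrame:
    """Whole sets in which every member has both blood pressures measured."""
    ok = df.groupby("set_id")[["sbp", "dbp"]].transform(lambda s: s.notna().all())
    keep_set = ok.all(axis=1)
    return df.loc[keep_set].copy()


def build_design(
    df: pd.DataFrame,
    spec: ModelSpec,
    params: StandardizationParams,
    require_case: bool = True,
) -> DesignMatrix:
    """Assemble the design matrix for one model.

    Metabolites and analyte covariates enter as standardized log2 z-scores
    (per-1-SD scale); categoricals are dummy-coded against their reference
    level; BMI and blood pressures enter per unit, mean-centered on the rows
    used (centering is invisible to the conditional likelihood but keeps
    interaction main effects interpretable; centers are recorded in ``meta``).
    Column order is deterministic: metabolites, covariates as listed,
    interaction columns last.
    """
    if spec.subset == "bp_complete":
        df = bp_complete_sets(df)
        if df.empty:
            raise ValueError("no sets with complete blood pressure data")
    elif spec.subset is not None:
        raise ValueError(f"unknown subset rule {spec.subset!r}")

    for cov in spec.covariates:
        if cov in schema.MATCHING_FACTORS:
            raise ValueError(
                f"{cov!r} is a matching factor; it is absorbed by the matched "
                "sets and cannot be a model covariate"
            )

    cols: dict[str, np.ndarray] = {}
    centers: dict[str, float] = {}

    z = apply_standardization(df, list(spec.metabolites), params)
    for m in spec.metabolites:
        cols[m] = z[m].to_numpy()

    for cov in spec.covariates:
        if cov in schema.CATEGORICAL_LEVELS:
            _add_dummies(cols, df, cov)
        elif cov in schema.ANALYTES:
            zc = apply_standardization(df, [cov], params)
            cols[cov] = zc[cov].to_numpy()
        elif cov in _NATURAL_SCALE:
            vals = df[cov].to_numpy(dtype=float)
            if np.isnan(vals).any():
                bad = df.index[np.isnan(vals)][:5].tolist()
                raise ValueError(f"missing {cov} in rows {bad}; filter sets first")
            centers[cov] = float(vals.mean())
            cols[cov] = vals - centers[cov]
        else:
            raise ValueError(f"unknown covariate {cov!r}")

    if spec.interaction is not None:
        met, modifier = spec.interaction
        if met not in spec.metabolites:
            raise ValueError(f"interaction metabolite {met!r} not in model")
        if modifier in schema.MATCHING_FACTORS and modifier != "sex":
            raise ValueError(
                f"{modifier!r} is a matching factor and cannot modify effects"
            )
        if modifier == "sex":
            # main effect absorbed by matching; only the product terms enter
            ref = schema.REFERENCE_LEVELS["sex"]
            _check_levels(df, "sex")
            for lev in schema.CATEGORICAL_LEVELS["sex"]:
                if lev != ref:
                    dummy = (df["sex"] == lev).to_numpy(dtype=float)
                    cols[f"{met}:sex[{lev}]"] = cols[met] * dummy
        elif modifier in schema.CATEGORICAL_LEVELS:
            if modifier not in spec.covariates:
                raise ValueError(
                    f"modifier {modifier!r} must be a covariate of the model"
                )
            ref = schema.REFERENCE_LEVELS[modifier]
            for lev in schema.CATEGORICAL_LEVELS[modifier]:
                if lev != ref:
                    dummy = (df[modifier] == lev).to_numpy(dtype=float)
                    cols[f"{met}:{modifier}[{lev}]"] = cols[met] * dummy
        elif modifier in _NATURAL_SCALE:
            if modifier not in spec.covariates:
                raise ValueError(
                    f"modifier {modifier!r} must be a covariate of the model"
                )
            cols[f"{met}:{modifier}"] = cols[met] * cols[modifier]
        else:
            raise ValueError(f"unknown modifier {modifier!r}")

    X = np.column_stack(list(cols.values()))
    meta = {"label": spec.label, "centers": centers, "n_sets": df["set_id"].nunique()}
    is_case = df["is_case"].to_numpy(dtype=bool) if require_case else None
    return make_design(X, list(cols.keys()), df["set_id"].to_numpy(), is_case, meta)


def _check_levels(df: pd.DataFrame, var: str) -> None:
    levels = set(schema.CATEGORICAL_LEVELS[var])
    bad = df.loc[~df[var].isin(levels) & df[var].notna()]
    if len(bad):
        row = bad.index[0]
        raise ValueError(
            f"unknown {var} level {bad[var].iloc[0]!r} at row {row}; "
            f"expected one of {sorted(levels)}"
        )
    if df[var].isna().any():
        row = df.index[df[var].isna()][0]
        raise ValueError(f"missing {var} at row {row}; filter sets first")


def _add_dummies(cols: dict, df: pd.DataFrame, var: str) -> None:
    _check_levels(df, var)
    ref = schema.REFERENCE_LEVELS[var]
    for lev in schema.CATEGORICAL_LEVELS[var]:
        if lev != ref:
            cols[f"{var}[{lev}]"] = (df[var] == lev).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# batteries


def _battery_row(label, summary, n_sets, converged, rhat_max):
    return {
        "model_label": label,
        "term": summary.name,
        "or": summary.or_estimate,
        "cri_low": summary.cri_low,
        "cri_high": summary.cri_high,
        "n_sets": n_sets,
        "converged": converged,
        "rhat_max": rhat_max,
    }


def fit_spec(
    df: pd.DataFrame,
    spec: ModelSpec,
    params: StandardizationParams,
    seed: int = 0,
    **sampler_kw,
) -> PosteriorDraws:
    """Build the design for ``spec`` and sample its posterior."""
    design = build_design(df, spec, params)
    draws = sample_posterior(design, prior=spec.prior, seed=seed, **sampler_kw)
    draws.meta["label"] = spec.label
    return draws


def _fit_and_summarize(
    df, spec, params, terms, seed, level, sampler_kw
) -> tuple[list[dict], PosteriorDraws]:
    draws = fit_spec(df, spec, params, seed=seed, **sampler_kw)
    n_sets = draws.meta.get("n_sets")
    rows = [
        _battery_row(
            spec.label,
            summarize_or(draws, t, level=level),
            n_sets,
            draws.converged,
            float(np.max(draws.rhat)),
        )
        for t in terms
    ]
    return rows, draws


def run_single_metabolite_models(
    df: pd.DataFrame,
    params: StandardizationParams,
    prior: PriorSpec | None = None,
    level: float = 0.90,
    seed: int = 0,
    **sampler_kw,
) -> pd.DataFrame:
    """Minimal and additionally adjusted models for each metabolite.

    Returns a tidy battery with one row per metabolite x model tier: the
    five-row, two-column grid of per-1-SD odds ratios.
    """
    prior = prior or PriorSpec()
    seeds = np.random.SeedSequence(seed).generate_state(2 * len(schema.METABOLITES))
    rows: list[dict] = []
    k = 0
    for met in schema.METABOLITES:
        for builder in (minimal_spec, additional_spec):
            spec = builder(met, prior=prior)
            new, _ = _fit_and_summarize(
                df, spec, params, [met], int(seeds[k] % 2**31), level, sampler_kw
            )
            rows += new
            k += 1
    return pd.DataFrame(rows)


def run_mutual_model(
    df: pd.DataFrame,
    params: StandardizationParams,
    prior: PriorSpec | None = None,
    level: float = 0.90,
    seed: int = 0,
    **sampler_kw,
) -> tuple[pd.DataFrame, PosteriorDraws]:
    """Fit the mutually adjusted model; returns the OR grid and the draws.

    The draws feed the profile contrasts and serve as the base model for
    effect-modifier comparisons.
    """
    spec = mutual_spec(prior=prior or PriorSpec())
    rows, draws = _fit_and_summarize(
        df, spec, params, list(schema.METABOLITES), seed, level, sampler_kw
    )
    return pd.DataFrame(rows), draws


def sensitivity_specs(prior: PriorSpec | None = None) -> list[ModelSpec]:
    prior = prior or PriorSpec()
    base = mutual_spec(prior=prior)
    return [
        replace(base, covariates=base.covariates + ("sbp",), subset="bp_complete",
                label="mutual+sbp"),
        replace(base, covariates=base.covariates + ("dbp",), subset="bp_complete",
                label="mutual+dbp"),
        replace(base, covariates=base.covariates + ("sbp", "dbp"),
                subset="bp_complete", label="mutual+sbp+dbp"),
        replace(base, covariates=base.covariates + ("sdma", "neopterin"),
                label="mutual+sdma+neopterin"),
        replace(base, covariates=tuple(c for c in base.covariates if c != "folate"),
                label="mutual-folate"),
    ]


def run_sensitivity(
    df: pd.DataFrame,
    params: StandardizationParams,
    prior: PriorSpec | None = None,
    level: float = 0.90,
    seed: int = 0,
    **sampler_kw,
) -> pd.DataFrame:
    """Sensitivity battery around the mutually adjusted model.

    Variants: +SBP, +DBP, +SBP+DBP (each on the blood-pressure-complete
    subset, whole sets only), +SDMA+neopterin, and folate removed.  Each row
    records the number of sets actually used.
    """
    specs = sensitivity_specs(prior)
    seeds = np.random.SeedSequence(seed).generate_state(len(specs))
    rows: list[dict] = []
    for s, spec in zip(seeds, specs):
        new, _ = _fit_and_summarize(
            df, spec, params, list(schema.METABOLITES), int(s % 2**31), level,
            sampler_kw,
        )
        rows += new
    return pd.DataFrame(rows)


__all__ = [
    "ModelSpec",
    "additional_spec",
    "bp_complete_sets",
    "build_design",
    "fit_spec",
    "minimal_spec",
    "mutual_spec",
    "run_mutual_model",
    "run_sensitivity",
    "run_single_metabolite_models",
    "sensitivity_specs",
]
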