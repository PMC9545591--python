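"""Synthetic matched case-control cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
correlated log-normal panel of eight circulating analytes calibrated to the
control arm of a published renal cell carcinoma nested case-control study
(medians and IQRs of the printed descriptive tables; homocysteine-cysteine
log-scale correlation 0.44), categorical and continuous covariates with the
control-arm frequencies, and a conditional-logistic outcome mechanism: within
each matched set, member j is labeled the case with probability
``exp(eta_j) / sum_k exp(eta_k)``, so the conditional likelihood fitted
downstream is the exact likelihood of the generated labels.

Defaults describe the sampled population under the null (``true_beta`` empty);
disease effects are an explicit experimental condition supplied by the caller,
e.g. :data:`EXAMPLE_TRUE_EFFECTS` for parameter-recovery studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import schema
from .models import ModelSpec, build_design, mutual_spec
from .preprocess import StandardizationParams

#: Normal-theory IQR -> SD conversion: Q3 - Q1 spans 2 * Phi^-1(0.75) SDs.
IQR_TO_SD = float(2.0 * stats.norm.ppf(0.75))

#: Control-arm medians (concentration units as measured: nmol/L for PLP,
#: folate and neopterin; umol/L otherwise).
CONTROL_MEDIANS: dict[str, float] = {
    "plp": 36.4,
    "homocysteine": 9.56,
    "serine": 97.7,
    "cystathionine": 0.180,
    "cysteine": 255.0,
    "folate": 12.0,
    "sdma": 0.440,
    "neopterin": 12.7,
}

#: Control-arm quartiles (Q1, Q3), same units.
CONTROL_IQRS: dict[str, tuple[float, float]] = {
    "plp": (25.6, 52.0),
    "homocysteine": (7.71, 11.40),
    "serine": (85.6, 112.5),
    "cystathionine": (0.130, 0.250),
    "cysteine": (232.0, 280.0),
    "folate": (8.6, 17.1),
    "sdma": (0.380, 0.500),
    "neopterin": (10.3, 15.8),
}

#: Effect preset for recovery studies: mutually adjusted per-1-SD log odds
#: ratios of plausible magnitude for a renal cancer metabolite panel
#: (protective PLP/serine/cysteine, adverse homocysteine/cystathionine).
EXAMPLE_TRUE_EFFECTS: dict[str, float] = {
    "plp": math.log(0.76),
    "homocysteine": math.log(1.10),
    "serine": math.log(0.90),
    "cystathionine": math.log(1.12),
    "cysteine": math.log(0.81),
}

_COUNTRY_PROBS = {
    "denmark": 109,
    "france": 8,
    "germany": 118,
    "italy": 86,
    "spain": 51,
    "netherlands": 43,
    "united_kingdom": 40,
}


def _default_log2_medians() -> dict[str, float]:
    return {a: math.log2(m) for a, m in CONTROL_MEDIANS.items()}


def _default_log2_sds() -> dict[str, float]:
    return {
        a: (math.log2(q3) - math.log2(q1)) / IQR_TO_SD
        for a, (q1, q3) in CONTROL_IQRS.items()
    }


def _default_corr() -> pd.DataFrame:
    """Exchangeable 0.2 between log analytes, 0.44 homocysteine-cysteine.

    Only the homocysteine-cysteine correlation is a printed calibration
    target; the weakly positive exchangeable background is a configurable
    placeholder for the unpublished full matrix.
    """
    names = list(schema.ANALYTES)
    k = len(names)
    corr = np.full((k, k), 0.2)
    np.fill_diagonal(corr, 1.0)
    c = pd.DataFrame(corr, index=names, columns=names)
    c.loc["homocysteine", "cysteine"] = c.loc["cysteine", "homocysteine"] = 0.44
    return c


def _default_covariate_dists() -> dict:
    """Control-arm category frequencies and continuous moments."""
    return {
        "education": {
            "primary_or_less": 173 / 455,
            "secondary": 59 / 455,
            "technical_professional": 111 / 455,
            "university": 112 / 455,
        },
        "fasting": {
            "not_fasting": 238 / 455,
            "in_between": 85 / 455,
            "fasting": 132 / 455,
        },
        "smoking": {"never": 199 / 455, "former": 148 / 455, "current": 108 / 455},
        "sex": {"male": 256 / 455, "female": 199 / 455},
        "country": {k: v / 455 for k, v in _COUNTRY_PROBS.items()},
        "bmi": {"mean": 26.2, "sd": (28.8 - 23.9) / IQR_TO_SD, "lo": 15.0, "hi": 60.0},
        "sbp": {"mean": 132.0, "sd": (147.0 - 120.0) / IQR_TO_SD, "lo": 70.0, "hi": 250.0},
        "dbp": {"mean": 82.0, "sd": (90.0 - 76.0) / IQR_TO_SD, "lo": 40.0, "hi": 150.0},
        "age": {"mean": 56.9, "sd": (61.8 - 51.9) / IQR_TO_SD, "lo": 20.0, "hi": 90.0},
    }


@dataclass
class GeneratorConfig:
    """Everything needed to simulate a matched cohort reproducibly.

    ``true_beta`` maps design-term names (as produced by the model-suite
    design builder, e.g. ``"plp"``, ``"education[university]"``, ``"bmi"``)
    to log odds ratios on the standardized scale; terms omitted are zero.
    ``interaction_gamma`` maps ``(metabolite, modifier)`` to the interaction
    coefficient.  ``bp_missing_rate`` masks both blood pressures jointly per
    subject (BP was simply not measured for some participants), while
    ``missing_rate`` masks each of the ``missable_fields`` independently.
    """

    n_sets: int = 455
    controls_per_case: int = 1
    log2_medians: dict[str, float] = field(default_factory=_default_log2_medians)
    log2_sds: dict[str, float] = field(default_factory=_default_log2_sds)
    corr: pd.DataFrame = field(default_factory=_default_corr)
    covariate_dists: dict = field(default_factory=_default_covariate_dists)
    true_beta: dict[str, float] = field(default_factory=dict)
    interaction_gamma: dict[tuple[str, str], float] = field(default_factory=dict)
    missing_rate: float = 0.0
    missable_fields: tuple[str, ...] = ("bmi", "smoking", "education")
    bp_missing_rate: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.controls_per_case < 1:
            raise ValueError("controls_per_case must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.bp_missing_rate < 1.0:
            raise ValueError("bp_missing_rate must be in [0, 1)")
        corr = self.corr.loc[list(schema.ANALYTES), list(schema.ANALYTES)].to_numpy()
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValueError("corr must have unit diagonal")
        w = np.linalg.eigvalsh(corr)
        if w.min() < -1e-10:
            raise ValueError(
                f"corr is not positive semi-definite: smallest eigenvalue {w.min():.3e}"
            )
        for var in ("education", "fasting", "smoking", "sex", "country"):
            probs = self.covariate_dists[var]
            total = float(sum(probs.values()))
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"{var} probabilities sum to {total!r}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{var} probabilities must be non-negative")
        for a in schema.ANALYTES:
            if self.log2_sds[a] < 0:
                raise ValueError(f"log2 SD for {a} must be >= 0")

    def standardization_params(self) -> StandardizationParams:
        """The location/scale actually used when computing linear predictors."""
        sds = {a: (s if s > 0 else 1.0) for a, s in self.log2_sds.items()}
        return StandardizationParams(
            mean_log2=dict(self.log2_medians), sd_log2=sds, population="generator"
        )


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery checks."""

    true_beta: dict[str, float]
    params: StandardizationParams
    config: GeneratorConfig
    assignment_spec: ModelSpec


def generate_panel(
    config: GeneratorConfig, n: int, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw ``n`` rows of analyte concentrations.

    Concentrations are ``2**v`` with ``v`` multivariate normal: means are the
    log2 medians, SDs the log2-scale IQR-derived SDs, correlation ``corr``.
    The log-normal median is therefore exactly the configured median.
    """
    config.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    names = list(schema.ANALYTES)
    corr = config.corr.loc[names, names].to_numpy()
    w, v = np.linalg.eigh(corr)
    factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n, len(names))) @ factor.T
    mu = np.array([config.log2_medians[a] for a in names])
    sd = np.array([config.log2_sds[a] for a in names])
    return pd.DataFrame(np.exp2(mu + z * sd), columns=names)


def _truncated_normal(rng, spec: Mapping[str, float], n: int) -> np.ndarray:
    a = (spec["lo"] - spec["mean"]) / spec["sd"]
    b = (spec["hi"] - spec["mean"]) / spec["sd"]
    u = rng.random(n)
    return stats.truncnorm.ppf(u, a, b, loc=spec["mean"], scale=spec["sd"])


def generate_covariates(
    config: GeneratorConfig, n: int, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw subject-level covariates (education, fasting, smoking, BMI, BP)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = {}
    for var in ("education", "fasting", "smoking"):
        probs = config.covariate_dists[var]
        levels = list(probs)
        out[var] = rng.choice(levels, size=n, p=[probs[l] for l in levels])
    for var in ("bmi", "sbp", "dbp"):
        out[var] = _truncated_normal(rng, config.covariate_dists[var], n)
    return pd.DataFrame(out)


def _assignment_spec(config: GeneratorConfig) -> ModelSpec:
    spec = mutual_spec()
    if config.interaction_gamma:
        if len(config.interaction_gamma) > 1:
            raise ValueError("at most one (metabolite, modifier) interaction pair")
        (pair,) = config.interaction_gamma
        spec = ModelSpec(
            metabolites=spec.metabolites,
            covariates=spec.covariates,
            interaction=pair,
            label="assignment",
        )
    return spec


def assign_case_within_sets(
    df: pd.DataFrame,
    true_beta: Mapping[str, float],
    spec: ModelSpec,
    params: StandardizationParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Label exactly one case per set, with conditional-logistic probabilities.

    Member j of a set becomes the case with probability
    ``exp(eta_j)/sum_k exp(eta_k)``, where eta is the design row (built on
    the standardized scale with ``params``) dotted with ``true_beta``.
    Sampling uses the Gumbel-max trick, which realizes exactly this softmax.
    """
    sizes = df.groupby("set_id", sort=False).size()
    if (sizes < 2).any():
        raise ValueError("every matched set needs at least 2 members")
    design = build_design(df, spec, params, require_case=False)
    unknown = set(true_beta) - set(design.columns)
    if unknown:
        raise KeyError(f"true_beta terms not in assignment design: {sorted(unknown)}")
    beta = np.array([float(true_beta.get(c, 0.0)) for c in design.columns])
    eta = design.X @ beta
    # design rows are sorted by set; map back to df order
    inv = np.empty(len(df), dtype=int)
    codes, _ = pd.factorize(df["set_id"].to_numpy())
    inv[np.argsort(codes, kind="stable")] = np.arange(len(df))
    eta_df = eta[inv]
    gumbel = rng.gumbel(size=len(df))
    score = pd.Series(eta_df + gumbel, index=df.index)
    winners = score.groupby(df["set_id"], sort=False).idxmax()
    out = df.copy()
    out["is_case"] = False
    out.loc[winners.to_numpy(), "is_case"] = True
    return out


def generate_cohort(
    config: GeneratorConfig, csv_path=None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a full matched cohort plus its ground-truth record.

    Matching attributes (country, sex, age, blood-draw date) are constant
    within each set by construction.  Missingness, applied after case
    assignment, is missing-completely-at-random.  With ``csv_path`` given the
    subject table is also written as CSV (byte-identical under a fixed seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.controls_per_case
    n = config.n_sets * (1 + m)

    panel = generate_panel(config, n, rng)
    covs = generate_covariates(config, n, rng)

    set_ids = np.repeat([f"set{i:05d}" for i in range(config.n_sets)], 1 + m)
    cd = config.covariate_dists
    country_p = cd["country"]
    sex_p = cd["sex"]
    per_set = {
        "country": rng.choice(list(country_p), size=config.n_sets,
                              p=list(country_p.values())),
        "sex": rng.choice(list(sex_p), size=config.n_sets, p=list(sex_p.values())),
        "age": np.round(_truncated_normal(rng, cd["age"], config.n_sets), 1),
        "blood_draw_date": np.round(1992.0 + 8.0 * rng.random(config.n_sets), 2),
    }

    df = pd.concat([panel, covs], axis=1)
    df.insert(0, "set_id", set_ids)
    df.insert(1, "subject_id", [f"sub{i:06d}" for i in range(n)])
    for k, v in per_set.items():
        df[k] = np.repeat(v, 1 + m)

    params = config.standardization_params()
    spec = _assignment_spec(config)
    beta = dict(config.true_beta)
    for (met, modifier), g in config.interaction_gamma.items():
        if modifier in schema.CATEGORICAL_LEVELS and modifier != "sex":
            for lev in schema.CATEGORICAL_LEVELS[modifier]:
                if lev != schema.REFERENCE_LEVELS[modifier]:
                    beta.setdefault(f"{met}:{modifier}[{lev}]", g)
        elif modifier == "sex":
            beta.setdefault(f"{met}:sex[female]", g)
        else:
            beta[f"{met}:{modifier}"] = g
    df = assign_case_within_sets(df, beta, spec, params, rng)

    bp_mask = rng.random(n) < config.bp_missing_rate
    df.loc[bp_mask, ["sbp", "dbp"]] = np.nan
    if config.missing_rate > 0:
        for fld in config.missable_fields:
            mask = rng.random(n) < config.missing_rate
            df.loc[mask, fld] = np.nan

    df = df[[c for c in schema.SUBJECT_COLUMNS]].copy()
    truth = GroundTruth(
        true_beta=beta, params=params, config=config, assignment_spec=spec
    )
    if csv_path is not None:
        from .report import write_subject_csv

        write_subject_csv(df, csv_path)
    return df, truth


__all__ = [
    "CONTROL_IQRS",
    "CONTROL_MEDIANS",
    "EXAMPLE_TRUE_EFFECTS",
    "GeneratorConfig",
    "GroundTruth",
    "IQR_TO_SD",
    "assign_case_within_sets",
    "generate_cohort",
    "generate_covariates",
    "generate_panel",
]
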