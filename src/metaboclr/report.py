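"""Descriptive statistics, subject CSV I/O and the end-to-end pipeline.

The subject CSV is the single data interchange format: one row per
participant, RFC-4180 with a header row, UTF-8, missing values as empty
fields (see :mod:`metaboclr.schema` for the column list).  ``run_pipeline``
executes the full analysis — complete-case filtering, standardization,
control correlations, the model batteries, profile contrasts, interaction
models with ELPD comparison and the sensitivity battery — and serializes
every result table as CSV alongside a JSON manifest recording the seed,
prior, exclusion log and convergence state.  Each table carries the config
hash so any number is traceable to the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema
from .bayes import PriorSpec
from .cohort import GeneratorConfig, generate_cohort
from .interactions import (
    contrast_at_modifier_level,
    elpd_compare,
    elpd_loo,
    fit_interaction_model,
    modifier_grid,
)
from .models import build_design, mutual_spec, run_mutual_model, run_sensitivity, \
    run_single_metabolite_models
from .preprocess import control_correlations, filter_complete_sets, fit_standardization
from .profiles import contrast_table, empirical_plp_profiles, profile_contrast, \
    theoretical_profile_sets

#: Fields a subject must have for the core analysis (BP handled separately).
REQUIRED_FIELDS = list(schema.ANALYTES) + ["education", "fasting", "smoking", "bmi"]

_CONTINUOUS_DESCRIPTIVES = list(schema.ANALYTES) + ["bmi", "sbp", "dbp", "age"]
_CATEGORICAL_DESCRIPTIVES = ["education", "fasting", "smoking", "sex", "country"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# descriptive statistics


def describe_cohort(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Baseline tables by case status.

    Categorical variables: counts and percentages per arm.  Continuous
    variables: median and interquartile range (Q1, Q3) per arm.
    """
    if df.empty:
        raise ValueError("empty cohort")
    is_case = df["is_case"].astype(bool)
    arms = {"cases": df.loc[is_case], "controls": df.loc[~is_case]}

    cat_rows = []
    for var in _CATEGORICAL_DESCRIPTIVES:
        if var not in df.columns:
            continue
        levels = schema.CATEGORICAL_LEVELS.get(var)
        if levels is None:
            levels = sorted(df[var].dropna().unique())
        for lev in levels:
            row = {"variable": var, "level": lev}
            for arm, sub in arms.items():
                n = int((sub[var] == lev).sum())
                denom = int(sub[var].notna().sum())
                row[f"{arm}_n"] = n
                row[f"{arm}_pct"] = 100.0 * n / denom if denom else np.nan
            cat_rows.append(row)

    cont_rows = []
    for var in _CONTINUOUS_DESCRIPTIVES:
        if var not in df.columns:
            continue
        row = {"variable": var}
        for arm, sub in arms.items():
            vals = sub[var].dropna()
            if len(vals):
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
            else:
                q1 = med = q3 = np.nan
            row[f"{arm}_median"] = med
            row[f"{arm}_q1"] = q1
            row[f"{arm}_q3"] = q3
        cont_rows.append(row)

    return {
        "categorical": pd.DataFrame(cat_rows),
        "continuous": pd.DataFrame(cont_rows),
    }


# ---------------------------------------------------------------------------
# subject CSV I/O


def write_subject_csv(df: pd.DataFrame, path) -> None:
    """Write the subject table in the canonical column order."""
    missing = [c for c in schema.SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject table lacks columns: {missing}")
    out = df[list(schema.SUBJECT_COLUMNS)].copy()
    out["is_case"] = out["is_case"].astype(bool).astype(int)
    out.to_csv(path, index=False)


def _validate_subjects(df: pd.DataFrame) -> None:
    dup = df["subject_id"][df.duplicated(["set_id", "subject_id"])]
    if len(dup):
        raise ValueError(f"duplicate (set_id, subject_id) keys: {dup.tolist()[:10]}")
    cases_per_set = df.groupby("set_id")["is_case"].sum()
    bad = cases_per_set[cases_per_set != 1]
    if len(bad):
        raise ValueError(
            "sets without exactly one case: "
            + ", ".join(f"{s} ({int(n)} cases)" for s, n in bad.head(10).items())
        )
    for a in schema.ANALYTES:
        nonpos = df.index[df[a].notna() & (df[a] <= 0)]
        if len(nonpos):
            raise ValueError(
                f"non-positive {a} at lines {[i + 2 for i in nonpos[:10]]}"
            )


def read_subject_csv(path) -> pd.DataFrame:
    """Read and validate a subject CSV; empty fields become missing values."""
    df = pd.read_csv(
        path, dtype={"set_id": str, "subject_id": str}, keep_default_na=True
    )
    missing = [c for c in schema.SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject CSV lacks columns: {missing}")
    df["is_case"] = df["is_case"].astype(int).astype(bool)
    _validate_subjects(df)
    return df


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """Configuration of one pipeline run (fully determined by the seed)."""

    cohort_csv: str | None = None
    generator: GeneratorConfig | None = None
    out_dir: str = "results"
    seed: int = 0
    n_chains: int = 4
    n_draws: int = 1000
    warmup: int = 500
    prior_scale: float = 2.5
    level: float = 0.90
    standardization_population: str = "all"
    run_descriptives: bool = True
    run_batteries: bool = True
    run_profiles: bool = True
    run_interactions: bool = True
    run_sensitivity: bool = True
    interaction_modifiers: tuple[str, ...] = ("bmi", "smoking")
    bmi_grid: tuple[float, ...] = (20.0, 25.0, 30.0, 35.0)

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, pd.DataFrame):
                return o.to_dict()
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # analysis-irrelevant
        blob = json.dumps(payload, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages and write all result tables.

    Returns the report bundle: a dict of DataFrames plus the manifest.  Any
    stage failure aborts with the stage name and the underlying cause.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log_lines: list[str] = []
    bundle: dict = {}
    manifest: dict = {
        "seed": config.seed,
        "config_hash": chash,
        "prior_scale": config.prior_scale,
        "level": config.level,
        "sampler": {
            "n_chains": config.n_chains,
            "n_draws": config.n_draws,
            "warmup": config.warmup,
        },
        "convergence": {},
    }
    sampler_kw = dict(
        n_chains=config.n_chains, n_draws=config.n_draws, warmup=config.warmup
    )
    prior = PriorSpec(scale=config.prior_scale)
    seeds = np.random.SeedSequence(config.seed).generate_state(16) % 2**31

    def log(msg: str) -> None:
        log_lines.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    def stage(name):
        def wrap(fn, *a, **kw):
            t0 = time.perf_counter()
            try:
                res = fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 - reported with stage name
                raise PipelineError(name, e) from e
            log(f"stage {name} done in {time.perf_counter() - t0:.2f}s")
            return res

        return wrap

    def save(name: str, table: pd.DataFrame) -> None:
        t = table.copy()
        t["config_hash"] = chash
        t.to_csv(out_dir / f"{name}.csv", index=False)
        bundle[name] = t

    # --- data
    if config.cohort_csv is not None:
        df = stage("load")(read_subject_csv, config.cohort_csv)
    elif config.generator is not None:
        df, truth = stage("simulate")(generate_cohort, config.generator)
        manifest["generator_true_beta"] = truth.true_beta
    else:
        raise PipelineError("load", ValueError("need cohort_csv or generator config"))
    log(f"loaded {len(df)} subjects in {df['set_id'].nunique()} sets")

    # --- filtering and standardization
    df, excl = stage("filter")(filter_complete_sets, df, REQUIRED_FIELDS)
    manifest["exclusions"] = {
        "n_sets_dropped": excl.n_sets_dropped,
        "n_subjects_dropped": excl.n_subjects_dropped,
        "missing_by_field": excl.missing_by_field,
    }
    log(excl.summary())
    params = stage("standardize")(
        fit_standardization, df, schema.ANALYTES, config.standardization_population
    )

    if config.run_descriptives:
        desc = stage("describe")(describe_cohort, df)
        save("descriptives_categorical", desc["categorical"])
        save("descriptives_continuous", desc["continuous"])

    corr = stage("correlations")(control_correlations, df)
    save("control_correlations", corr.reset_index(names="analyte"))

    mutual_draws = None
    if config.run_batteries or config.run_profiles or config.run_interactions:
        battery, mutual_draws = stage("mutual_model")(
            run_mutual_model, df, params, prior=prior, level=config.level,
            seed=int(seeds[0]), **sampler_kw,
        )
        manifest["convergence"]["mutual"] = bool(mutual_draws.converged)
        save("mutual_model", battery)

    if config.run_batteries:
        singles = stage("single_metabolite_models")(
            run_single_metabolite_models, df, params, prior=prior,
            level=config.level, seed=int(seeds[1]), **sampler_kw,
        )
        save("single_metabolite_models", singles)

    if config.run_profiles:
        def _profiles():
            sets = {"empirical_plp": empirical_plp_profiles(df, params)}
            sets.update(theoretical_profile_sets())
            rows = []
            for pset in sets.values():
                rows.append(
                    contrast_table(
                        profile_contrast(mutual_draws, pset, level=config.level)
                    )
                )
            return pd.concat(rows, ignore_index=True)

        save("profile_contrasts", stage("profiles")(_profiles))

    if config.run_interactions:
        def _interactions():
            base_design = build_design(df, mutual_spec(prior=prior), params)
            base_elpd = elpd_loo(mutual_draws, base_design)
            rows = []
            k = 2
            for modifier in config.interaction_modifiers:
                for met in schema.METABOLITES:
                    draws, design = fit_interaction_model(
                        df, params, met, modifier, prior=prior,
                        seed=int(seeds[k % 16]), **sampler_kw,
                    )
                    k += 1
                    comp = elpd_compare(elpd_loo(draws, design), base_elpd)
                    for lev in modifier_grid(modifier, config.bmi_grid):
                        s = contrast_at_modifier_level(
                            draws, met, modifier, lev, cri_level=config.level
                        )
                        rows.append(
                            {
                                "metabolite": met,
                                "modifier": modifier,
                                "level": lev,
                                "or": s.or_estimate,
                                "cri_low": s.cri_low,
                                "cri_high": s.cri_high,
                                "elpd_diff": comp.elpd_diff,
                                "se_diff": comp.se_diff,
                                "converged": draws.converged,
                            }
                        )
            return pd.DataFrame(rows)

        save("interactions", stage("interactions")(_interactions))

    if config.run_sensitivity:
        sens = stage("sensitivity")(
            run_sensitivity, df, params, prior=prior, level=config.level,
            seed=int(seeds[15]), **sampler_kw,
        )
        save("sensitivity", sens)

    manifest["tables"] = sorted(bundle.keys())
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    bundle["manifest"] = manifest
    return bundle


__all__ = [
    "PipelineError",
    "REQUIRED_FIELDS",
    "RunConfig",
    "describe_cohort",
    "read_subject_csv",
    "run_pipeline",
    "write_subject_csv",
]
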