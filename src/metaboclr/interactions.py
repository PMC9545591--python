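"""Effect modification and leave-one-set-out predictive model comparison.

Each interaction model is the mutually adjusted model plus product terms
between one metabolite's z-score and one modifier ("separate interaction
terms": one metabolite at a time).  Modifier-specific odds ratios are linear
contrasts of the posterior draws: for a continuous modifier centered at c,
the per-1-SD log-OR at modifier value v is ``beta_met + gamma * (v - c)``;
for a categorical modifier it is ``beta_met + gamma_level``.

Model fit is compared by expected log predictive density (ELPD) with the
matched set as the exchangeable unit: leave-one-set-out cross-validation
approximated by Pareto-smoothed importance sampling over the posterior
draws, with exact refits available for sets whose importance weights are
unreliable.  Comparisons are reported as interaction-model minus base-model,
so a negative difference means the interaction terms worsen predictive fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import schema
from .bayes import (
    DesignMatrix,
    OrSummary,
    PosteriorDraws,
    PriorSpec,
    sample_posterior,
    summarize_or,
)
from .models import ModelSpec, build_design, mutual_spec
from .preprocess import StandardizationParams

#: Default BMI evaluation grid (kg/m^2) for modifier-specific odds ratios.
BMI_GRID = (20.0, 25.0, 30.0, 35.0)

PARETO_K_THRESHOLD = 0.7


@dataclass
class ElpdResult:
    """Per-set leave-one-set-out ELPD contributions and diagnostics."""

    per_set: np.ndarray
    pareto_k: np.ndarray
    set_labels: np.ndarray
    method: str = "psis-loo"

    @property
    def total(self) -> float:
        return float(self.per_set.sum())

    @property
    def n_sets(self) -> int:
        return len(self.per_set)

    @property
    def bad_sets(self) -> np.ndarray:
        return np.flatnonzero(self.pareto_k > PARETO_K_THRESHOLD)

    @property
    def flagged(self) -> bool:
        return len(self.bad_sets) > 0.10 * self.n_sets


@dataclass
class ElpdComparison:
    """Paired ELPD difference (model A minus model B) with its SE."""

    elpd_diff: float
    se_diff: float
    n_sets: int
    method: str = "psis-loo"


def interaction_spec(
    metabolite: str, modifier: str, prior: PriorSpec | None = None
) -> ModelSpec:
    """Mutually adjusted model plus one metabolite x modifier interaction."""
    base = mutual_spec(prior=prior or PriorSpec())
    covariates = base.covariates
    if modifier in ("sbp", "dbp") and modifier not in covariates:
        covariates = covariates + (modifier,)
    return ModelSpec(
        metabolites=base.metabolites,
        covariates=covariates,
        interaction=(metabolite, modifier),
        subset="bp_complete" if modifier in ("sbp", "dbp") else None,
        prior=base.prior,
        label=f"mutual+{metabolite}x{modifier}",
    )


def fit_interaction_model(
    df: pd.DataFrame,
    params: StandardizationParams,
    metabolite: str,
    modifier: str,
    prior: PriorSpec | None = None,
    seed: int = 0,
    **sampler_kw,
) -> tuple[PosteriorDraws, DesignMatrix]:
    """Fit one interaction-augmented model; returns draws and its design."""
    spec = interaction_spec(metabolite, modifier, prior)
    design = build_design(df, spec, params)
    draws = sample_posterior(design, prior=spec.prior, seed=seed, **sampler_kw)
    draws.meta.update(design.meta)
    draws.meta["interaction"] = (metabolite, modifier)
    return draws, design


def contrast_at_modifier_level(
    draws: PosteriorDraws,
    metabolite: str,
    modifier: str,
    level,
    cri_level: float = 0.90,
) -> OrSummary:
    """Per-1-SD OR of the metabolite at a given modifier value or category."""
    contrast = {metabolite: 1.0}
    if modifier in schema.CATEGORICAL_LEVELS:
        if level not in schema.CATEGORICAL_LEVELS[modifier]:
            raise KeyError(f"{level!r} is not a level of {modifier!r}")
        if level != schema.REFERENCE_LEVELS[modifier]:
            term = f"{metabolite}:{modifier}[{level}]"
            if term not in draws.term_names:
                raise KeyError(f"model has no interaction term {term!r}")
            contrast[term] = 1.0
    else:
        term = f"{metabolite}:{modifier}"
        if term not in draws.term_names:
            raise KeyError(f"model has no interaction term {term!r}")
        center = draws.meta.get("centers", {}).get(modifier, 0.0)
        contrast[term] = float(level) - center
    return summarize_or(
        draws, contrast, level=cri_level,
        name=f"{metabolite}@{modifier}={level}",
    )


def _set_loglik_matrix(draws: PosteriorDraws, design: DesignMatrix) -> np.ndarray:
    """(n_sets, n_draws) conditional log-likelihood of each set per draw."""
    if design.case_rows is None:
        raise ValueError("design has no case labels")
    eta = design.X @ draws.draws.T  # (n_rows, D)
    m = np.maximum.reduceat(eta, design.starts, axis=0)
    lse = m + np.log(
        np.add.reduceat(np.exp(eta - m[design.row_block]), design.starts, axis=0)
    )
    return eta[design.case_rows, :] - lse


def elpd_loo(draws: PosteriorDraws, design: DesignMatrix) -> ElpdResult:
    """Leave-one-set-out ELPD by Pareto-smoothed importance sampling.

    Raw importance weights for dropping set s are 1/p(case_s | beta); the
    smoothed log-weights are combined with the per-set log-likelihoods to
    give each set's out-of-sample log predictive density.  Sets whose Pareto
    k exceeds 0.7 are unreliable; :func:`elpd_exact_refit` recomputes them.
    """
    ll = _set_loglik_matrix(draws, design)
    reff = float(np.mean(draws.ess)) / draws.draws.shape[0]
    lw, k = az.psislw(-ll, reff=min(1.0, max(reff, 1e-3)))
    lw = np.asarray(lw)
    k = np.asarray(k)
    per_set = logsumexp(lw + ll, axis=1)
    return ElpdResult(per_set=per_set, pareto_k=k, set_labels=design.set_labels)


def elpd_exact_refit(
    design: DesignMatrix,
    prior: PriorSpec | None = None,
    set_indices=None,
    seed: int = 0,
    **sampler_kw,
) -> np.ndarray:
    """Exact leave-one-set-out ELPD contributions by refitting.

    For each held-out set, the posterior is re-sampled without it and the
    set's ELPD is the log posterior-mean conditional probability of its
    observed case.  Brute force; intended for validation and for sets the
    importance-sampling diagnostics flag.
    """
    prior = prior or PriorSpec()
    if set_indices is None:
        set_indices = range(design.n_sets)
    set_indices = list(set_indices)
    seeds = np.random.SeedSequence(seed).generate_state(len(set_indices))
    out = np.empty(len(set_indices))
    full_rows = np.arange(design.X.shape[0])
    for i, s in enumerate(set_indices):
        reduced = design.drop_sets([s])
        d = sample_posterior(
            reduced, prior=prior, seed=int(seeds[i] % 2**31), **sampler_kw
        )
        rows = full_rows[design.row_block == s]
        Xs = design.X[rows]
        eta = Xs @ d.draws.T  # (m_s, D)
        case_row = int(np.searchsorted(rows, design.case_rows[s]))
        logp = eta[case_row] - logsumexp(eta, axis=0)
        out[i] = logsumexp(logp) - np.log(len(logp))
    return out


def elpd_compare(a: ElpdResult, b: ElpdResult) -> ElpdComparison:
    """Paired comparison of two models on the same sets (A minus B).

    ``se_diff = sqrt(n) * SD(per-set differences)``; identical models give a
    difference of exactly 0 with SE 0.
    """
    if a.n_sets != b.n_sets or not np.array_equal(a.set_labels, b.set_labels):
        raise ValueError("ELPD comparisons require the same sets in the same order")
    d = a.per_set - b.per_set
    n = len(d)
    se = float(np.sqrt(n) * np.std(d, ddof=1)) if n > 1 else 0.0
    return ElpdComparison(
        elpd_diff=float(d.sum()), se_diff=se, n_sets=n,
        method=f"{a.method} vs {b.method}",
    )


def modifier_grid(modifier: str, bmi_grid=BMI_GRID):
    """Default evaluation points for a modifier."""
    if modifier in schema.CATEGORICAL_LEVELS:
        return schema.CATEGORICAL_LEVELS[modifier]
    if modifier == "bmi":
        return tuple(bmi_grid)
    raise ValueError(f"no default grid for modifier {modifier!r}")


__all__ = [
    "BMI_GRID",
    "ElpdComparison",
    "ElpdResult",
    "PARETO_K_THRESHOLD",
    "contrast_at_modifier_level",
    "elpd_compare",
    "elpd_exact_refit",
    "elpd_loo",
    "fit_interaction_model",
    "interaction_spec",
    "modifier_grid",
]
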