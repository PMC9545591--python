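"""Complete-case filtering, log2 standardization and control-arm correlations.

Analyte concentrations enter every regression on the per-1-SD scale: each
concentration is log2 transformed, centered and scaled to unit standard
deviation.  Odds ratios downstream are therefore "per 1 SD increase in log
concentration".  Pearson correlations between metabolites are estimated on the
log scale among controls only, the non-diseased sampling frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import ANALYTES, METABOLITES


class NoInformativeSetsError(ValueError):
    """Raised when complete-case filtering leaves no matched sets."""


@dataclass
class StandardizationParams:
    """Per-analyte location and scale of log2 concentration.

    ``z = (log2(x) - mean_log2) / sd_log2``.  Fitted means and SDs use the
    n-1 denominator.  ``population`` records which subjects the parameters
    were estimated from (e.g. ``"all"``, ``"controls"`` or ``"generator"``).
    """

    mean_log2: dict[str, float]
    sd_log2: dict[str, float]
    population: str = "all"

    def __post_init__(self) -> None:
        for name, sd in self.sd_log2.items():
            if not sd > 0:
                raise ValueError(f"sd_log2 must be positive for {name!r}, got {sd}")

    @property
    def analytes(self) -> list[str]:
        return list(self.mean_log2)


@dataclass
class ExclusionLog:
    """Book-keeping for complete-case filtering, sets dropped whole."""

    n_sets_in: int
    n_sets_kept: int
    n_subjects_in: int
    n_subjects_kept: int
    missing_by_field: dict[str, int] = field(default_factory=dict)
    dropped_sets: list = field(default_factory=list)

    @property
    def n_sets_dropped(self) -> int:
        return self.n_sets_in - self.n_sets_kept

    @property
    def n_subjects_dropped(self) -> int:
        return self.n_subjects_in - self.n_subjects_kept

    def summary(self) -> str:
        lines = [
            f"sets: {self.n_sets_in} in, {self.n_sets_kept} kept, "
            f"{self.n_sets_dropped} dropped",
            f"subjects: {self.n_subjects_in} in, {self.n_subjects_kept} kept, "
            f"{self.n_subjects_dropped} dropped",
        ]
        for fld, n in sorted(self.missing_by_field.items()):
            lines.append(f"  missing {fld}: {n} subjects")
        return "\n".join(lines)


def filter_complete_sets(
    df: pd.DataFrame, required_fields: list[str]
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop every matched set containing any subject missing a required field.

    Sets are dropped whole: in conditional-likelihood inference a 1:1 set with
    one incomplete member contributes nothing, and partial sets would break
    the one-case-per-set invariant.  Raises :class:`NoInformativeSetsError`
    when nothing survives.
    """
    missing = [c for c in required_fields if c not in df.columns]
    if missing:
        raise KeyError(f"required fields not in table: {missing}")

    incomplete = df[required_fields].isna().any(axis=1)
    bad_sets = df.loc[incomplete, "set_id"].unique()
    keep = ~df["set_id"].isin(bad_sets)
    out = df.loc[keep].copy()

    dropped_rows = df.loc[~keep]
    by_field = {
        f: int(dropped_rows[f].isna().sum())
        for f in required_fields
        if dropped_rows[f].isna().any()
    }
    log = ExclusionLog(
        n_sets_in=df["set_id"].nunique(),
        n_sets_kept=out["set_id"].nunique(),
        n_subjects_in=len(df),
        n_subjects_kept=len(out),
        missing_by_field=by_field,
        dropped_sets=list(bad_sets),
    )
    if out.empty:
        raise NoInformativeSetsError(
            "no matched sets remain after complete-case filtering:\n" + log.summary()
        )
    return out, log


def log2_standardize(
    values, params: tuple[float, float] | None = None
) -> tuple[np.ndarray, tuple[float, float]]:
    """log2-transform, center and scale one analyte column to SD 1.

    When ``params`` (mean_log2, sd_log2) is given it is applied as-is;
    otherwise both are fitted from ``values`` and returned.  Non-positive
    concentrations and zero-variance columns are rejected.
    """
    arr = np.asarray(values, dtype=float)
    bad = np.where(~(arr > 0))[0]
    if bad.size:
        labels = (
            list(values.index[bad]) if isinstance(values, pd.Series) else bad.tolist()
        )
        raise ValueError(f"non-positive concentration at rows {labels[:10]}")
    logv = np.log2(arr)
    if params is None:
        if np.unique(arr).size < 2:
            raise ValueError("zero variance: need >= 2 distinct values to fit scale")
        mean, sd = float(np.mean(logv)), float(np.std(logv, ddof=1))
        if sd == 0:
            raise ValueError("zero variance on log2 scale")
        params = (mean, sd)
    mean, sd = params
    if not sd > 0:
        raise ValueError(f"sd_log2 must be positive, got {sd}")
    return (logv - mean) / sd, params


def fit_standardization(
    df: pd.DataFrame,
    analytes: tuple[str, ...] = ANALYTES,
    population: str = "all",
) -> StandardizationParams:
    """Fit per-analyte log2 mean/SD on the given subjects.

    ``population="controls"`` restricts the fit to control subjects; the
    default uses every retained subject (cases and controls).
    """
    sub = df if population == "all" else df.loc[~df["is_case"].astype(bool)]
    means, sds = {}, {}
    for a in analytes:
        _, (m, s) = log2_standardize(sub[a])
        means[a], sds[a] = m, s
    return StandardizationParams(mean_log2=means, sd_log2=sds, population=population)


def apply_standardization(
    df: pd.DataFrame, analytes: list[str], params: StandardizationParams
) -> pd.DataFrame:
    """Return a DataFrame of z-scored log2 concentrations for ``analytes``."""
    out = {}
    for a in analytes:
        z, _ = log2_standardize(df[a], (params.mean_log2[a], params.sd_log2[a]))
        out[a] = z
    return pd.DataFrame(out, index=df.index)


def control_correlations(
    df: pd.DataFrame, analytes: tuple[str, ...] = METABOLITES
) -> pd.DataFrame:
    """Pearson correlation matrix of log-transformed analytes among controls.

    Pearson correlation is invariant to the linear center/scale step and to
    the base of the logarithm, so the matrix equals the correlation of the
    standardized values.
    """
    controls = df.loc[~df["is_case"].astype(bool), list(analytes)]
    if len(controls) < 3:
        raise ValueError(f"need >= 3 control subjects, got {len(controls)}")
    if (controls <= 0).any().any():
        raise ValueError("non-positive concentrations among controls")
    return np.log2(controls).corr(method="pearson")
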