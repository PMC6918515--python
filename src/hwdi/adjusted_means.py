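"""Survey-weighted, covariate-adjusted mean BMI per state and income group.

BMI is regressed (weighted least squares, survey weights as case weights)
on indicator-coded age, race/ethnicity, sex, education, plus the 3-level
income group of the chosen scheme.  Group means come from marginal
standardization (g-computation): set every respondent's income group to g,
predict, and take the survey-weighted mean of the predictions.  The
overall mean predicts at the observed groups, which for a least-squares
fit with an intercept equals the weighted raw mean of BMI.  Per-dataset
estimates from a multiple-imputation stack are pooled by their arithmetic
mean, with within/between variance recorded for diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _schema as S

logger = logging.getLogger(__name__)

__all__ = [
    "FittedBMIModel",
    "PooledEstimate",
    "StateGroupMeans",
    "fit_bmi_model",
    "marginal_mean",
    "pool_over_imputations",
    "compute_state_group_means",
]

#: Adjustment covariates and their coded level sets (reference = first level).
ADJUSTMENT_COVARIATES = {
    S.AGE: S.AGE_LEVELS,
    S.RACE: S.RACE_LEVELS,
    S.SEX: S.SEX_LEVELS,
    S.EDUCATION: S.EDUCATION_LEVELS,
}


@dataclass
class FittedBMIModel:
    group_column: str
    columns: list  # (variable, level) pairs, intercept first as ("const", None)
    coefficients: np.ndarray
    dropped: list = field(default_factory=list)

    def design(self, df: pd.DataFrame, group_override: str | None = None) -> np.ndarray:
        cols = []
        for var, level in self.columns:
            if var == "const":
                cols.append(np.ones(len(df)))
            elif var == self.group_column:
                if group_override is not None:
                    cols.append(np.full(len(df), 1.0 if group_override == level else 0.0))
                else:
                    cols.append((df[var].to_numpy() == level).astype(float))
            else:
                cols.append((df[var].to_numpy(dtype=float) == level).astype(float))
        return np.column_stack(cols)

    def predict(self, df: pd.DataFrame, group_override: str | None = None) -> np.ndarray:
        return self.design(df, group_override) @ self.coefficients


def fit_bmi_model(df: pd.DataFrame, group_column: str, weights=None) -> FittedBMIModel:
    """Weighted least squares of BMI on the adjustment covariates and the
    income group (reference = first level of each factor).

    Columns that are constant in the data (single-level factors, empty
    groups) are dropped with a warning; the fit proceeds on the reduced
    design.
    """
    w = df[S.WEIGHT].to_numpy(dtype=float) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    y = df[S.BMI].to_numpy(dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError("fit_bmi_model requires complete BMI")

    columns: list = [("const", None)]
    for var, levels in ADJUSTMENT_COVARIATES.items():
        columns += [(var, lv) for lv in levels[1:]]
    columns += [(group_column, g) for g in S.GROUPS[1:]]

    model = FittedBMIModel(group_column=group_column, columns=columns, coefficients=np.zeros(0))
    X = model.design(df)
    # Drop aliased/constant indicator columns (never the intercept).
    keep = [0] + [j for j in range(1, X.shape[1]) if X[:, j].min() != X[:, j].max()]
    dropped = [model.columns[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        logger.warning("dropping constant design columns: %s", dropped)
    model.columns = [model.columns[j] for j in keep]
    model.dropped = dropped
    X = X[:, keep]

    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    model.coefficients = beta
    return model


def marginal_mean(model: FittedBMIModel, df: pd.DataFrame, weights=None, target: str = "overall") -> float:
    """Marginally standardized mean BMI.

    ``target='overall'`` predicts at the observed income groups;
    ``target=<group>`` sets every respondent's group to that level first.
    Returns NaN (non-computable) when the requested group is empty in the
    fitted data.
    """
    w = df[S.WEIGHT].to_numpy(dtype=float) if weights is None else np.asarray(weights, dtype=float)
    if target == "overall":
        pred = model.predict(df)
    else:
        if target not in S.GROUPS:
            raise ValueError(f"unknown target {target!r}")
        present = set(df[model.group_column].dropna().unique())
        if target not in present:
            return float("nan")
        pred = model.predict(df, group_override=target)
    return float(np.average(pred, weights=w))


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    within_variance: float
    between_variance: float
    m: int

    @property
    def total_variance(self) -> float:
        """Rubin total variance W + (1 + 1/m) B."""
        return self.within_variance + (1.0 + 1.0 / self.m) * self.between_variance


def pool_over_imputations(estimates: Sequence[float], variances: Sequence[float] | None = None) -> PooledEstimate:
    """Pool per-dataset estimates of one estimand: the arithmetic mean, with
    between-imputation variance (and within, when per-dataset variances are
    supplied) recorded for diagnostics.  Any non-finite component makes the
    pooled estimate non-computable (NaN)."""
    est = np.asarray(list(estimates), dtype=float)
    m = len(est)
    if m < 1:
        raise ValueError("need at least one estimate")
    if not np.all(np.isfinite(est)):
        return PooledEstimate(float("nan"), float("nan"), float("nan"), m)
    point = float(est.mean())
    between = float(est.var(ddof=1)) if m > 1 else 0.0
    within = float(np.mean(variances)) if variances is not None else 0.0
    return PooledEstimate(point, within, between, m)


@dataclass
class StateGroupMeans:
    """Pooled adjusted means for one state under one scheme."""

    state: str
    scheme: str
    overall: float
    group_means: dict  # group -> pooled mean (NaN = non-computable)
    group_n_unweighted: dict
    group_n_weighted: dict
    m_pooled_over: int
    between_variance: dict = field(default_factory=dict)

    @property
    def computable(self) -> bool:
        vals = [self.overall] + [self.group_means[g] for g in S.GROUPS]
        return bool(np.all(np.isfinite(vals)))


def compute_state_group_means(
    datasets: Sequence[pd.DataFrame],
    scheme: str,
    adjusted: bool = True,
    at_covariate_means: bool = False,
) -> StateGroupMeans:
    """Adjusted (or crude) mean BMI overall and per income group for one
    state, pooled across the ``m`` completed datasets.

    ``adjusted=False`` uses survey-weighted raw group means instead of the
    regression model.  ``at_covariate_means=True`` predicts at the weighted
    covariate means rather than averaging per-respondent predictions; for
    this linear model the two variants coincide (kept as a cross-check).
    """
    if scheme not in S.SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    group_col = S.HWDI_GROUP if scheme == S.SCHEME_HWDI else S.RHWDI_GROUP
    per_overall: list[float] = []
    per_group: dict[str, list[float]] = {g: [] for g in S.GROUPS}
    n_unw = {g: 0.0 for g in S.GROUPS}
    n_w = {g: 0.0 for g in S.GROUPS}
    state = str(datasets[0][S.STATE].iloc[0])

    for ds in datasets:
        w = ds[S.WEIGHT].to_numpy(dtype=float)
        if adjusted:
            model = fit_bmi_model(ds, group_col)
            if at_covariate_means:
                per_overall.append(_at_means_prediction(model, ds, w, None))
            else:
                per_overall.append(marginal_mean(model, ds, w, "overall"))
            for g in S.GROUPS:
                if at_covariate_means:
                    present = set(ds[group_col].dropna().unique())
                    val = _at_means_prediction(model, ds, w, g) if g in present else float("nan")
                else:
                    val = marginal_mean(model, ds, w, g)
                per_group[g].append(val)
        else:
            per_overall.append(float(np.average(ds[S.BMI].to_numpy(dtype=float), weights=w)))
            for g in S.GROUPS:
                mask = (ds[group_col] == g).to_numpy()
                per_group[g].append(
                    float(np.average(ds[S.BMI].to_numpy(dtype=float)[mask], weights=w[mask]))
                    if mask.any()
                    else float("nan")
                )
        for g in S.GROUPS:
            mask = (ds[group_col] == g).to_numpy()
            n_unw[g] += int(mask.sum())
            n_w[g] += float(w[mask].sum())

    m = len(datasets)
    pooled_overall = pool_over_imputations(per_overall)
    pooled_groups = {g: pool_over_imputations(per_group[g]) for g in S.GROUPS}
    return StateGroupMeans(
        state=state,
        scheme=scheme,
        overall=pooled_overall.estimate,
        group_means={g: pooled_groups[g].estimate for g in S.GROUPS},
        group_n_unweighted={g: n_unw[g] / m for g in S.GROUPS},
        group_n_weighted={g: n_w[g] / m for g in S.GROUPS},
        m_pooled_over=m,
        between_variance={"overall": pooled_overall.between_variance}
        | {g: pooled_groups[g].between_variance for g in S.GROUPS},
    )


def _at_means_prediction(model: FittedBMIModel, df: pd.DataFrame, w: np.ndarray, group: str | None) -> float:
    """Predict at the weighted mean design row (equals g-computation for a
    linear model; retained as an alternate code path)."""
    X = model.design(df, group_override=group)
    xbar = np.average(X, axis=0, weights=w)
    return float(xbar @ model.coefficients)
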