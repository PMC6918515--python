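"""Multiple imputation by chained equations, run separately per state.

Per-variable methods: Bayesian linear regression for continuous variables
(BMI, adults and children in household), predictive mean matching for the
ordinal variables (education, income category), and logistic regression
for sex.  Race/ethnicity is never imputed: records missing it are dropped
case-wise before imputation.  The survey weight enters every conditional
model as a regular predictor.

Each of the ``m`` completed datasets gets its own deterministic random
stream derived from the master seed, so an identical (data, spec) pair
reproduces the stack bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _schema as S

logger = logging.getLogger(__name__)

__all__ = ["ImputationSpec", "ImputedStack", "UnimputableStateError", "impute_chained", "pmm_step"]

METHOD_LINEAR = "linear_regression"
METHOD_PMM = "pmm"
METHOD_LOGISTIC = "logistic"

#: Imputation method per variable; race/ethnicity is deliberately absent.
VARIABLE_METHODS = {
    S.BMI: METHOD_LINEAR,
    S.N_CHILDREN: METHOD_LINEAR,
    S.N_ADULTS: METHOD_LINEAR,
    S.EDUCATION: METHOD_PMM,
    S.INCOME: METHOD_PMM,
    S.SEX: METHOD_LOGISTIC,
}

#: Count-valued variables whose linear-regression draws are rounded to
#: non-negative integers.
_COUNT_VARIABLES = (S.N_ADULTS, S.N_CHILDREN)


class UnimputableStateError(RuntimeError):
    """A modeled variable has too few observed values to impute."""


@dataclass
class ImputationSpec:
    m_datasets: int = 20
    cycles_per_dataset: int = 10
    pmm_donor_count: int = 5
    include_weight_as_predictor: bool = True
    min_observed: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.m_datasets < 1:
            raise ValueError("m_datasets must be >= 1")
        if self.cycles_per_dataset < 1:
            raise ValueError("cycles_per_dataset must be >= 1")
        if self.pmm_donor_count < 1:
            raise ValueError("pmm_donor_count must be >= 1")


@dataclass
class ImputedStack:
    """The ``m`` completed datasets for one state plus their seed trail."""

    state: str
    datasets: list[pd.DataFrame]
    seeds: list[tuple[int, int]]
    n_dropped_casewise: int = 0
    imputed_variables: tuple[str, ...] = ()

    @property
    def m(self) -> int:
        return len(self.datasets)


def _draw_ols_coefficients(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """OLS fit plus a draw from the approximate coefficient posterior.

    Returns (beta_hat, beta_draw, sigma_draw).  The noise variance is drawn
    from its scaled inverse-chi-square posterior; coefficients from the
    conditional normal.  A tiny ridge keeps near-singular designs usable.
    """
    n, k = X.shape
    xtx = X.T @ X + 1e-8 * np.eye(k)
    xtx_inv = np.linalg.inv(xtx)
    beta_hat = xtx_inv @ (X.T @ y)
    resid = y - X @ beta_hat
    df = max(n - k, 1)
    sse = float(resid @ resid)
    sigma2 = max(sse, 1e-12) / max(rng.chisquare(df), 1e-12)
    try:
        L = np.linalg.cholesky(xtx_inv)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(xtx_inv + 1e-10 * np.eye(k))
    beta_draw = beta_hat + np.sqrt(sigma2) * (L @ rng.standard_normal(k))
    return beta_hat, beta_draw, float(np.sqrt(sigma2))


def _pmm_match(
    pred_obs: np.ndarray,
    pred_mis: np.ndarray,
    y_obs: np.ndarray,
    donor_count: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Donor matching on predicted means.

    For each missing case, the ``donor_count`` observed cases with predicted
    means nearest the missing case's prediction form the donor pool (ties in
    distance broken by lowest observed-case index); one donor value is drawn
    uniformly.
    """
    k = min(donor_count, len(y_obs))
    out = np.empty(len(pred_mis))
    idx = np.arange(len(pred_obs))
    for j, pm in enumerate(pred_mis):
        dist = np.abs(pred_obs - pm)
        order = np.lexsort((idx, dist))  # distance first, then index
        pool = order[:k]
        out[j] = y_obs[pool[rng.integers(k)]]
    return out


def pmm_step(
    target: np.ndarray,
    predictors: np.ndarray,
    donor_count: int,
    seed_or_rng,
) -> np.ndarray:
    """Predictive-mean-matching fill of one variable.

    ``target`` is a 1-D array with NaN at missing entries; ``predictors`` a
    complete 2-D design (an intercept column is added internally).  Observed
    cases keep the OLS predictions; missing cases are predicted under a
    posterior coefficient draw, then matched to observed donors.  Imputed
    values are always members of the observed value set.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    y = np.asarray(target, dtype=float)
    X = np.column_stack([np.ones(len(y)), np.asarray(predictors, dtype=float)])
    miss = np.isnan(y)
    if not miss.any():
        return y.copy()
    obs = ~miss
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise UnimputableStateError("pmm_step: no observed values")
    if n_obs < donor_count:
        logger.warning("pmm_step: only %d observed cases; lowering donor count", n_obs)
    beta_hat, beta_draw, _ = _draw_ols_coefficients(X[obs], y[obs], rng)
    pred_obs = X[obs] @ beta_hat
    pred_mis = X[miss] @ beta_draw
    out = y.copy()
    out[miss] = _pmm_match(pred_obs, pred_mis, y[obs], donor_count, rng)
    return out


def _linear_step(y, X, rng, count_variable=False):
    miss = np.isnan(y)
    obs = ~miss
    _, beta_draw, sigma = _draw_ols_coefficients(X[obs], y[obs], rng)
    draws = X[miss] @ beta_draw + sigma * rng.standard_normal(int(miss.sum()))
    if count_variable:
        draws = np.maximum(np.round(draws), 0.0)
    out = y.copy()
    out[miss] = draws
    return out


def _logistic_step(y, X, rng):
    """Impute a binary variable coded {1, 2}; falls back to an
    observed-frequency draw on separation or non-convergence."""
    import statsmodels.api as sm

    miss = np.isnan(y)
    obs = ~miss
    y01 = (y[obs] == 2).astype(float)
    out = y.copy()
    n_mis = int(miss.sum())
    if y01.min() == y01.max():  # single observed class
        out[miss] = 2.0 if y01.max() == 1 else 1.0
        return out
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y01, X[obs]).fit(disp=0, maxiter=50)
            cov = np.asarray(fit.cov_params())
            if not np.all(np.isfinite(cov)) or not np.all(np.isfinite(fit.params)):
                raise np.linalg.LinAlgError("non-finite logistic fit")
            L = np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))
            beta = np.asarray(fit.params) + L @ rng.standard_normal(cov.shape[0])
            p = 1.0 / (1.0 + np.exp(-(X[miss] @ beta)))
    except Exception as exc:  # separation / singular fit
        logger.warning("logistic imputation fell back to frequency draw: %s", exc)
        p = np.full(n_mis, float(y01.mean()))
    out[miss] = np.where(rng.random(n_mis) < p, 2.0, 1.0)
    return out


def _design_matrix(df: pd.DataFrame, exclude: str, include_weight: bool) -> np.ndarray:
    """Intercept + all analysis variables except ``exclude``; race/ethnicity
    is dummy-coded (reference level 1), ordinals and counts enter numerically."""
    cols = [np.ones(len(df))]
    for var in S.ANALYSIS_VARIABLES:
        if var == exclude:
            continue
        if var == S.RACE:
            codes = df[S.RACE].to_numpy(dtype=float)
            for level in S.RACE_LEVELS[1:]:
                cols.append((codes == level).astype(float))
        else:
            cols.append(df[var].to_numpy(dtype=float))
    if include_weight:
        cols.append(df[S.WEIGHT].to_numpy(dtype=float))
    return np.column_stack(cols)


def impute_chained(records: pd.DataFrame, spec: ImputationSpec) -> ImputedStack:
    """Run chained-equations imputation on one state's records.

    Records missing race/ethnicity (or the survey weight, which every
    conditional model needs) are dropped case-wise first.  Variables are
    visited in order of ascending missingness.  Observed values are never
    altered; with nothing to impute every completed dataset equals the
    input.
    """
    spec.validate()
    states = records[S.STATE].dropna().unique()
    state = str(states[0]) if len(states) else ""
    if len(states) > 1:
        raise ValueError("impute_chained expects records from a single state")

    keep = records[S.RACE].notna() & records[S.WEIGHT].notna() & records[S.AGE].notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("state %s: %d records dropped case-wise (race/weight/age missing)", state, n_dropped)
    base = records.loc[keep].copy()

    to_impute = [v for v in VARIABLE_METHODS if base[v].isna().any()]
    for var in to_impute:
        n_obs = int(base[var].notna().sum())
        if n_obs == 0 or n_obs < spec.min_observed:
            raise UnimputableStateError(
                f"state {state!r}: variable {var!r} has {n_obs} observed values "
                f"(minimum {spec.min_observed})"
            )
    # Ascending missingness, name as deterministic tie-break.
    to_impute.sort(key=lambda v: (int(base[v].isna().sum()), v))

    datasets: list[pd.DataFrame] = []
    seeds: list[tuple[int, int]] = []
    for m_index in range(spec.m_datasets):
        seeds.append((spec.seed, m_index))
        if not to_impute:
            datasets.append(base.copy())
            continue
        rng = np.random.default_rng([spec.seed, m_index])
        work = base.copy()
        # Initialize missing entries with draws from the observed values.
        for var in to_impute:
            y = work[var].to_numpy(dtype=float)
            miss = np.isnan(y)
            obs_vals = y[~miss]
            y[miss] = rng.choice(obs_vals, size=int(miss.sum()), replace=True)
            work[var] = y
        for _ in range(spec.cycles_per_dataset):
            for var in to_impute:
                y = work[var].to_numpy(dtype=float).copy()
                y[base[var].isna().to_numpy()] = np.nan  # re-expose the holes
                X = _design_matrix(work, exclude=var, include_weight=spec.include_weight_as_predictor)
                method = VARIABLE_METHODS[var]
                if method == METHOD_LINEAR:
                    filled = _linear_step(y, X, rng, count_variable=var in _COUNT_VARIABLES)
                    if var == S.BMI:
                        filled = np.maximum(filled, 1.0)  # keep BMI physically positive
                elif method == METHOD_PMM:
                    filled = pmm_step(y, X[:, 1:], spec.pmm_donor_count, rng)
                else:
                    filled = _logistic_step(y, X, rng)
                work[var] = filled
        datasets.append(work)
    return ImputedStack(
        state=state,
        datasets=datasets,
        seeds=seeds,
        n_dropped_casewise=n_dropped,
        imputed_variables=tuple(to_impute),
    )
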