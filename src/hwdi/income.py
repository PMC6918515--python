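"""Income handling: dollar assignment, poverty-guideline ratios, and the two
low/middle/high classification schemes.

The fixed-dollar scheme uses national income cut points ($35,000 and
$75,000) applied identically everywhere.  The poverty-ratio scheme is
state-referenced: *low* is at or below 185% of the federal poverty
guideline for the household's size and region, *high* is above the
state-specific 75th percentile of the poverty-ratio distribution, and
*middle* is everything in between.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _schema as S

logger = logging.getLogger(__name__)

__all__ = [
    "INCOME_CATEGORY_TOP_DOLLARS",
    "LOW_INCOME_POVERTY_PCT",
    "HIGH_INCOME_PERCENTILE",
    "REGIONS",
    "PovertyGuidelineTable",
    "region_for_state",
    "assign_income_dollars",
    "poverty_ratio",
    "classify_hwdi_groups",
    "classify_rhwdi_groups",
    "percentile_75",
    "add_income_classification",
]

#: Highest dollar value possible in each of the 8 ordinal income categories;
#: the open-ended top category is floored at its lower bound.
INCOME_CATEGORY_TOP_DOLLARS = (9999, 14999, 19999, 24999, 34999, 49999, 74999, 75000)

#: Poverty-ratio cut (percent of guideline) between low and middle income.
LOW_INCOME_POVERTY_PCT = 185.0

#: Within-state percentile of the poverty-ratio distribution above which a
#: respondent is classified high income.
HIGH_INCOME_PERCENTILE = 75.0

REGION_CONTIGUOUS = "contiguous_and_DC"
REGION_ALASKA = "alaska"
REGION_HAWAII = "hawaii"
REGIONS = (REGION_CONTIGUOUS, REGION_ALASKA, REGION_HAWAII)


class IncomeValidationError(ValueError):
    """Raised for out-of-range income categories or invalid inputs."""


@dataclass(frozen=True)
class PovertyGuidelineTable:
    """Per-region poverty guideline: base dollars for a one-person household
    plus a fixed increment per additional person."""

    year: int
    base_dollars: Mapping[str, float]
    increment_dollars: Mapping[str, float]

    def __post_init__(self) -> None:
        for region in REGIONS:
            if region not in self.base_dollars or region not in self.increment_dollars:
                raise IncomeValidationError(f"guideline table missing region {region!r}")
            if self.base_dollars[region] <= 0:
                raise IncomeValidationError(f"base_dollars must be > 0 for {region!r}")
            if self.increment_dollars[region] <= 0:
                raise IncomeValidationError(f"increment_dollars must be > 0 for {region!r}")

    def guideline(self, region: str, household_size) -> float:
        """Guideline dollars for a household of the given size (size >= 1)."""
        size = np.asarray(household_size, dtype=float)
        if np.any(size < 1):
            raise IncomeValidationError("household_size must be >= 1")
        out = self.base_dollars[region] + (size - 1) * self.increment_dollars[region]
        return float(out) if out.ndim == 0 else out


def region_for_state(state: str) -> str:
    """Map a state label to its guideline region (Alaska and Hawaii have
    their own guideline rows; everything else uses the contiguous table)."""
    s = str(state).strip().lower()
    if s in ("alaska", "ak"):
        return REGION_ALASKA
    if s in ("hawaii", "hi"):
        return REGION_HAWAII
    return REGION_CONTIGUOUS


def assign_income_dollars(income_category):
    """Dollar income assigned to an ordinal income category (1..8): the
    highest value possible in the category's range.

    Accepts a scalar or an array; NaNs propagate.
    """
    cats = np.asarray(income_category, dtype=float)
    scalar = cats.ndim == 0
    cats = np.atleast_1d(cats)
    valid = ~np.isnan(cats)
    if np.any((cats[valid] < 1) | (cats[valid] > 8) | (cats[valid] != np.round(cats[valid]))):
        raise IncomeValidationError("income_category must be an integer in 1..8")
    out = np.full(cats.shape, np.nan)
    table = np.asarray(INCOME_CATEGORY_TOP_DOLLARS, dtype=float)
    out[valid] = table[cats[valid].astype(int) - 1]
    return float(out[0]) if scalar else out


def poverty_ratio(assigned_income, household_size, state, guidelines: PovertyGuidelineTable):
    """Income as a percent of the poverty guideline for the household's size
    in the state's guideline region: ``100 * income / guideline(size)``."""
    region = region_for_state(state)
    g = guidelines.guideline(region, household_size)
    return 100.0 * np.asarray(assigned_income, dtype=float) / g


def classify_hwdi_groups(income_category):
    """Fixed-dollar scheme: categories 1-5 (< $35,000) are low, 6-7 are
    middle, 8 (>= $75,000) is high.  NaN categories yield None."""
    cats = np.asarray(income_category, dtype=float)
    scalar = cats.ndim == 0
    cats = np.atleast_1d(cats)
    valid = ~np.isnan(cats)
    if np.any((cats[valid] < 1) | (cats[valid] > 8)):
        raise IncomeValidationError("income_category must be in 1..8")
    out = np.where(cats <= 5, S.GROUP_LOW, np.where(cats <= 7, S.GROUP_MIDDLE, S.GROUP_HIGH))
    out = out.astype(object)
    out[~valid] = None
    return out[0] if scalar else out


def percentile_75(values: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """75th percentile of ``values``.

    Unweighted (default): the averaged-inverted-CDF definition — with
    ``h = 0.75 * n`` an integer the result averages the h-th and (h+1)-th
    order statistics, otherwise it is the ceil(h)-th order statistic.
    Weighted: the analogous definition on the weighted CDF.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0 or np.any(np.isnan(x)):
        raise IncomeValidationError("percentile requires non-empty, non-missing values")
    p = HIGH_INCOME_PERCENTILE / 100.0
    if weights is None:
        return float(np.percentile(x, HIGH_INCOME_PERCENTILE, method="averaged_inverted_cdf"))
    w = np.asarray(weights, dtype=float)
    if w.shape != x.shape or np.any(w <= 0):
        raise IncomeValidationError("weights must be positive and match values")
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    cdf = np.cumsum(ws) / np.sum(ws)
    i = int(np.searchsorted(cdf, p, side="left"))
    if i + 1 < xs.size and abs(cdf[i] - p) < 1e-12:
        return float((xs[i] + xs[i + 1]) / 2.0)
    return float(xs[min(i, xs.size - 1)])


def classify_rhwdi_groups(
    ratios: Sequence[float],
    weights: Sequence[float] | None = None,
    weighted_percentile: bool = False,
    state: str | None = None,
):
    """Poverty-ratio scheme for one state's respondents.

    low: ratio <= 185; middle: 185 < ratio <= p75(state); high: ratio > p75.
    The 75th percentile is computed on the same population being classified.
    A degenerate state (p75 <= 185) proceeds with an empty middle group and
    a logged warning.
    """
    x = np.asarray(ratios, dtype=float)
    valid = ~np.isnan(x)
    if not np.any(valid):
        raise IncomeValidationError("at least one non-missing ratio required")
    w = None
    if weighted_percentile:
        if weights is None:
            raise IncomeValidationError("weighted percentile requires weights")
        w = np.asarray(weights, dtype=float)[valid]
    p75 = percentile_75(x[valid], w)
    if p75 <= LOW_INCOME_POVERTY_PCT:
        logger.warning(
            "degenerate poverty-ratio distribution%s: p75=%.2f <= %.0f; middle group will be empty",
            f" in state {state!r}" if state else "",
            p75,
            LOW_INCOME_POVERTY_PCT,
        )
    out = np.where(
        x <= LOW_INCOME_POVERTY_PCT,
        S.GROUP_LOW,
        np.where(x <= p75, S.GROUP_MIDDLE, S.GROUP_HIGH),
    ).astype(object)
    out[~valid] = None
    return out


def add_income_classification(
    df: pd.DataFrame,
    guidelines: PovertyGuidelineTable,
    weighted_percentile: bool = False,
) -> pd.DataFrame:
    """Append assigned income, poverty ratio, and both group labels to a
    (completed) microdata frame.  The poverty-ratio percentile is computed
    within each state."""
    out = df.copy()
    out[S.ASSIGNED_INCOME] = assign_income_dollars(out[S.INCOME].to_numpy())
    size = out[S.N_ADULTS].to_numpy(dtype=float) + out[S.N_CHILDREN].to_numpy(dtype=float)
    size = np.maximum(size, 1.0)  # guideline defined for household size >= 1
    ratio = np.full(len(out), np.nan)
    for region in REGIONS:
        mask = out[S.STATE].map(region_for_state).to_numpy() == region
        if mask.any():
            g = guidelines.guideline(region, size[mask])
            ratio[mask] = 100.0 * out[S.ASSIGNED_INCOME].to_numpy()[mask] / g
    out[S.POVERTY_RATIO] = ratio
    out[S.HWDI_GROUP] = classify_hwdi_groups(out[S.INCOME].to_numpy())
    out[S.RHWDI_GROUP] = None
    for state, idx in out.groupby(S.STATE).groups.items():
        sub = out.loc[idx]
        labels = classify_rhwdi_groups(
            sub[S.POVERTY_RATIO].to_numpy(),
            weights=sub[S.WEIGHT].to_numpy(),
            weighted_percentile=weighted_percentile,
            state=str(state),
        )
        out.loc[idx, S.RHWDI_GROUP] = labels
    return out
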