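"""Respondent exclusions and state-eligibility screening applied before any
statistical stage.

Respondents are excluded if pregnant, outside the coded 18-64 age range, or
underweight (BMI < 18.5).  A record missing one of those fields is NOT
excluded by that criterion — missing data are handled downstream by
imputation.  States are screened for excess missingness and for empty
income-by-race crosstab cells; ineligible states are dropped from all
later stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _schema as S

logger = logging.getLogger(__name__)

__all__ = ["ExclusionTally", "StateEligibility", "apply_exclusions", "assess_state_eligibility"]

#: Attribution order when a record matches several exclusion criteria.
EXCLUSION_ORDER = ("pregnant", "age_over_65", "underweight_bmi")

UNDERWEIGHT_BMI_CUTOFF = 18.5

REASON_EXCESS_MISSINGNESS = "excess_missingness"
REASON_ZERO_CROSSTAB_CELL = "zero_crosstab_cell"


@dataclass(frozen=True)
class ExclusionTally:
    pregnant: int
    age_over_65: int
    underweight_bmi: int
    retained: int

    @property
    def excluded(self) -> int:
        return self.pregnant + self.age_over_65 + self.underweight_bmi

    @property
    def total(self) -> int:
        return self.excluded + self.retained


@dataclass(frozen=True)
class StateEligibility:
    state: str
    eligible: bool
    reasons: tuple[str, ...]

    def __post_init__(self):
        assert self.eligible == (len(self.reasons) == 0)


def apply_exclusions(df: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionTally]:
    """Drop pregnant, out-of-age-range, and underweight respondents.

    Multi-reason records are tallied once, under the first matching reason
    in :data:`EXCLUSION_ORDER`.  Records missing a criterion field pass that
    criterion.  Pure filter: calling it twice equals calling it once.
    """
    pregnant = df[S.PREGNANT].to_numpy(dtype=float) == 1
    age = df[S.AGE].to_numpy(dtype=float)
    bad_age = ~np.isnan(age) & ~np.isin(age, np.asarray(S.AGE_LEVELS, dtype=float))
    bmi = df[S.BMI].to_numpy(dtype=float)
    underweight = ~np.isnan(bmi) & (bmi < UNDERWEIGHT_BMI_CUTOFF)

    first_pregnant = pregnant
    first_age = bad_age & ~pregnant
    first_under = underweight & ~pregnant & ~bad_age
    keep = ~(pregnant | bad_age | underweight)

    tally = ExclusionTally(
        pregnant=int(first_pregnant.sum()),
        age_over_65=int(first_age.sum()),
        underweight_bmi=int(first_under.sum()),
        retained=int(keep.sum()),
    )
    logger.info(
        "exclusions: %d pregnant, %d out-of-age-range, %d underweight; %d retained of %d",
        tally.pregnant, tally.age_over_65, tally.underweight_bmi, tally.retained, len(df),
    )
    return df.loc[keep].copy(), tally


def _zero_crosstab_cell(sub: pd.DataFrame) -> bool:
    """True if the observed income-category x race/ethnicity table has an
    empty cell whose row and column marginals are both nonzero."""
    obs = sub[[S.INCOME, S.RACE]].dropna()
    if obs.empty:
        return True
    table = pd.crosstab(obs[S.INCOME], obs[S.RACE])
    # Marginals are nonzero for every level present in the table.
    return bool((table.to_numpy() == 0).any())


def assess_state_eligibility(
    df: pd.DataFrame, missing_threshold: float = 0.5, states=None
) -> list[StateEligibility]:
    """Screen each state for analysis eligibility.

    A state is flagged ``excess_missingness`` when any analysis variable has
    a missing fraction strictly above ``missing_threshold`` (default 0.5),
    and ``zero_crosstab_cell`` when the observed income-by-race table has an
    empty cell with nonzero marginals.  A state with zero records (possible
    when an expected ``states`` list is supplied) gets both reasons.
    """
    if not 0 < missing_threshold <= 1:
        raise ValueError("missing_threshold must be in (0, 1]")
    if states is None:
        states = df[S.STATE].dropna().unique()
    out: list[StateEligibility] = []
    for state in sorted(states, key=str):
        sub = df[df[S.STATE] == state]
        reasons: list[str] = []
        if len(sub) == 0:
            logger.warning("state %r has zero records", state)
            reasons = [REASON_EXCESS_MISSINGNESS, REASON_ZERO_CROSSTAB_CELL]
        else:
            frac = sub[list(S.ANALYSIS_VARIABLES)].isna().mean()
            if (frac > missing_threshold).any():
                worst = frac.idxmax()
                logger.info("state %r: %.0f%% missing on %s", state, 100 * frac.max(), worst)
                reasons.append(REASON_EXCESS_MISSINGNESS)
            if _zero_crosstab_cell(sub):
                reasons.append(REASON_ZERO_CROSSTAB_CELL)
        out.append(StateEligibility(state=str(state), eligible=not reasons, reasons=tuple(reasons)))
    for e in out:
        if not e.eligible:
            logger.info("state %s ineligible: %s", e.state, ", ".join(e.reasons))
    return out
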