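"""Synthetic survey-microdata generator with known, configurable structure.

Produces BRFSS-style respondent records (demographics, 8-level ordinal
household income, household composition, continuous BMI, survey weight)
with a controllable income-to-BMI gradient, per-state BMI shifts, and a
separate missingness injector (MCAR or missing-at-random on the survey
weight).  Because the generating parameters are known, every downstream
stage can be tested against ground truth without any external data.

The income-group effect is injected through the fixed-dollar income
grouping (categories 1-5 / 6-7 / 8), so the configured low/middle/high BMI
gaps are recoverable from complete data without reference to the simulated
poverty-ratio classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _schema as S
from .income import classify_hwdi_groups

__all__ = ["GeneratorConfig", "MissingnessSpec", "generate_population", "inject_missingness"]


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the bad field."""


def _normalized(values) -> tuple[float, ...]:
    a = np.asarray(values, dtype=float)
    return tuple(a / a.sum())


# Default categorical margins (normalized percentages of US adults 18-64).
_DEFAULT_AGE = _normalized((15.2, 21.3, 20.6, 21.6, 21.3))
_DEFAULT_SEX = _normalized((49.2, 50.8))  # male, female
_DEFAULT_RACE = _normalized((58.5, 12.2, 5.5, 1.6, 1.6, 18.6))
_DEFAULT_EDUCATION = _normalized((13.4, 27.7, 31.5, 27.3))
_DEFAULT_INCOME = _normalized((6.2, 5.1, 7.6, 8.9, 9.8, 12.9, 14.7, 34.2))

_DEFAULT_HOUSEHOLD = {
    (1, 0): 0.25,
    (2, 0): 0.30,
    (1, 1): 0.05,
    (2, 1): 0.12,
    (2, 2): 0.13,
    (2, 3): 0.04,
    (3, 0): 0.08,
    (4, 0): 0.03,
}

_MARGIN_LENGTHS = {
    S.AGE: len(S.AGE_LEVELS),
    S.SEX: len(S.SEX_LEVELS),
    S.RACE: len(S.RACE_LEVELS),
    S.EDUCATION: len(S.EDUCATION_LEVELS),
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic population.

    ``income_category_probs`` may be a single 8-vector shared by all states
    or a mapping from state label to 8-vector; likewise ``bmi_base`` may be
    a scalar or a per-state mapping.  ``bmi_income_gradient`` is the
    additive BMI effect of the (low, middle, high) fixed-dollar income
    groups.  ``covariate_bmi_effects`` maps a covariate name to one
    additive effect per coded level.
    """

    states: Sequence[str] = ("Alabama", "California", "Florida", "New York", "Texas")
    n_per_state: int = 1000
    income_category_probs: Sequence[float] | Mapping[str, Sequence[float]] = _DEFAULT_INCOME
    bmi_base: float | Mapping[str, float] = 27.6
    bmi_income_gradient: tuple[float, float, float] = (1.2, 0.5, 0.0)
    covariate_margins: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            S.AGE: _DEFAULT_AGE,
            S.SEX: _DEFAULT_SEX,
            S.RACE: _DEFAULT_RACE,
            S.EDUCATION: _DEFAULT_EDUCATION,
        }
    )
    covariate_bmi_effects: Mapping[str, Sequence[float]] = field(default_factory=dict)
    bmi_noise_sd: float = 4.5
    household_size_dist: Mapping[tuple[int, int], float] = field(
        default_factory=lambda: dict(_DEFAULT_HOUSEHOLD)
    )
    weight_dispersion: float = 0.5
    pregnancy_rate: float = 0.03
    seed: int = 0

    def income_probs_for(self, state: str) -> np.ndarray:
        if isinstance(self.income_category_probs, Mapping):
            return np.asarray(self.income_category_probs[state], dtype=float)
        return np.asarray(self.income_category_probs, dtype=float)

    def bmi_base_for(self, state: str) -> float:
        if isinstance(self.bmi_base, Mapping):
            return float(self.bmi_base[state])
        return float(self.bmi_base)

    def validate(self) -> None:
        if self.n_per_state < 0:
            raise ConfigurationError("n_per_state must be >= 0")
        if self.bmi_noise_sd < 0:
            raise ConfigurationError("bmi_noise_sd must be >= 0")
        if self.weight_dispersion <= 0:
            raise ConfigurationError("weight_dispersion must be > 0")
        if not 0 <= self.pregnancy_rate <= 1:
            raise ConfigurationError("pregnancy_rate must be in [0, 1]")
        if len(self.bmi_income_gradient) != 3:
            raise ConfigurationError("bmi_income_gradient must have 3 entries (low, middle, high)")
        for state in self.states:
            p = self.income_probs_for(state)
            if p.shape != (8,):
                raise ConfigurationError("income_category_probs must have 8 entries")
            _check_probs("income_category_probs", p)
        for name, length in _MARGIN_LENGTHS.items():
            p = np.asarray(self.covariate_margins[name], dtype=float)
            if p.shape != (length,):
                raise ConfigurationError(f"covariate_margins[{name}] must have {length} entries")
            _check_probs(f"covariate_margins[{name}]", p)
        for name, effects in self.covariate_bmi_effects.items():
            if name not in _MARGIN_LENGTHS:
                raise ConfigurationError(f"covariate_bmi_effects names unknown covariate {name!r}")
            if len(effects) != _MARGIN_LENGTHS[name]:
                raise ConfigurationError(
                    f"covariate_bmi_effects[{name}] must have {_MARGIN_LENGTHS[name]} entries"
                )
        hh = np.asarray(list(self.household_size_dist.values()), dtype=float)
        _check_probs("household_size_dist", hh)
        for (a, c) in self.household_size_dist:
            if a < 0 or c < 0 or a + c < 1:
                raise ConfigurationError("household_size_dist keys must give household size >= 1")


def _check_probs(name: str, p: np.ndarray) -> None:
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} must be non-negative and sum to 1 (got sum {p.sum()!r})")


def generate_population(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a complete (no missing values) synthetic population.

    BMI is built additively: per-state base + fixed-dollar income-group
    gradient + covariate effects + Gaussian noise.  Survey weights are
    log-normal, normalized to mean 1 within each state.  Identical config
    and seed give bitwise-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    frames = []
    gradient = {g: float(v) for g, v in zip(S.GROUPS, config.bmi_income_gradient)}
    for state in config.states:
        n = config.n_per_state
        if n == 0:
            continue
        cols: dict = {S.STATE: np.repeat(str(state), n)}
        for name in (S.AGE, S.SEX, S.RACE, S.EDUCATION):
            levels = np.asarray(S.CATEGORICAL_LEVELS[name], dtype=float)
            p = np.asarray(config.covariate_margins[name], dtype=float)
            cols[name] = rng.choice(levels, size=n, p=p)
        cols[S.INCOME] = rng.choice(
            np.asarray(S.INCOME_LEVELS, dtype=float), size=n, p=config.income_probs_for(state)
        )
        hh_keys = list(config.household_size_dist.keys())
        hh_p = np.asarray(list(config.household_size_dist.values()), dtype=float)
        hh_idx = rng.choice(len(hh_keys), size=n, p=hh_p)
        cols[S.N_ADULTS] = np.asarray([hh_keys[i][0] for i in hh_idx], dtype=float)
        cols[S.N_CHILDREN] = np.asarray([hh_keys[i][1] for i in hh_idx], dtype=float)

        bmi = np.full(n, config.bmi_base_for(state))
        groups = classify_hwdi_groups(cols[S.INCOME])
        bmi += np.asarray([gradient[g] for g in groups])
        for name, effects in config.covariate_bmi_effects.items():
            eff = np.asarray(effects, dtype=float)
            bmi += eff[cols[name].astype(int) - 1]
        bmi += rng.normal(0.0, config.bmi_noise_sd, size=n)
        cols[S.BMI] = bmi

        pregnant = np.zeros(n)
        female = cols[S.SEX] == 2
        pregnant[female] = (rng.random(int(female.sum())) < config.pregnancy_rate).astype(float)
        cols[S.PREGNANT] = pregnant

        w = rng.lognormal(mean=0.0, sigma=config.weight_dispersion, size=n)
        cols[S.WEIGHT] = w / w.mean()
        frames.append(pd.DataFrame(cols))
    if not frames:
        return pd.DataFrame(columns=list(S.MICRODATA_COLUMNS))
    out = pd.concat(frames, ignore_index=True)
    return out[list(S.MICRODATA_COLUMNS)]


@dataclass
class MissingnessSpec:
    """Per-variable missingness rates and mechanism.

    ``MCAR`` masks each targeted value independently with the given rate.
    ``MAR-on-weight`` makes the masking probability increase linearly in the
    within-dataset rank of the survey weight while keeping the mean
    probability exactly at the rate: p_i = rate + slope * (u_i - 1/2) with
    u_i the mid-rank percentile of the weight and slope = 2*min(rate, 1-rate).
    """

    rates: Mapping[str, float]
    mechanism: str = "MCAR"
    seed: int = 0

    MECHANISMS = ("MCAR", "MAR-on-weight")

    def validate(self) -> None:
        if self.mechanism not in self.MECHANISMS:
            raise ConfigurationError(f"mechanism must be one of {self.MECHANISMS}")
        for name, rate in self.rates.items():
            if name not in S.MICRODATA_COLUMNS or name == S.STATE:
                raise ConfigurationError(f"cannot inject missingness into column {name!r}")
            if not 0 <= rate <= 1:
                raise ConfigurationError(f"rate for {name!r} must be in [0, 1]")


def mar_probabilities(weights: np.ndarray, rate: float) -> np.ndarray:
    """Masking probabilities for the MAR-on-weight mechanism (mean exactly
    ``rate``, non-decreasing in weight)."""
    n = len(weights)
    ranks = np.argsort(np.argsort(weights, kind="stable"), kind="stable")
    u = (ranks + 0.5) / n
    slope = 2.0 * min(rate, 1.0 - rate)
    return rate + slope * (u - 0.5)


def inject_missingness(df: pd.DataFrame, spec: MissingnessSpec) -> pd.DataFrame:
    """Mask values per the spec; never alters a value, only replaces it with
    NaN.  Realized fractions vary by binomial sampling error around the
    configured rates."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out = df.copy()
    for name, rate in spec.rates.items():
        if rate == 0:
            continue
        if spec.mechanism == "MCAR":
            p = np.full(len(out), rate)
        else:
            p = mar_probabilities(df[S.WEIGHT].to_numpy(dtype=float), rate)
        mask = rng.random(len(out)) < p
        out.loc[mask, name] = np.nan
    return out
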