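import numpy as np
import pandas as pd
import pytest

from hwdi import _schema as S
from hwdi.income import PovertyGuidelineTable
from hwdi.interface import load_poverty_guidelines, load_table2_fixture
from hwdi.synthetic_data import GeneratorConfig, generate_population

#: Margins with no rare cells, so small synthetic states pass the
#: income-by-race zero-cell eligibility screen.
BALANCED_MARGINS = {
    S.AGE: (0.2, 0.2, 0.2, 0.2, 0.2),
    S.SEX: (0.492, 0.508),
    S.RACE: (0.4, 0.2, 0.1, 0.1, 0.1, 0.1),
    S.EDUCATION: (0.25, 0.25, 0.25, 0.25),
}
BALANCED_INCOME = (0.07, 0.08, 0.09, 0.09, 0.09, 0.14, 0.14, 0.30)


def balanced_config(**overrides) -> GeneratorConfig:
    kwargs = dict(
        states=("Alaska", "California", "Hawaii", "New York", "Texas"),
        n_per_state=1000,
        covariate_margins=BALANCED_MARGINS,
        income_category_probs=BALANCED_INCOME,
        bmi_income_gradient=(2.0, 0.0, 0.0),
        bmi_noise_sd=3.0,
        seed=0,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def make_records(n=None, **columns) -> pd.DataFrame:
    """Small hand-built microdata frame; unspecified columns get benign
    defaults."""
    if n is None:
        n = max(len(np.atleast_1d(v)) for v in columns.values()) if columns else 1
    defaults = {
        S.STATE: "Texas",
        S.AGE: 3.0,
        S.SEX: 1.0,
        S.RACE: 1.0,
        S.EDUCATION: 2.0,
        S.INCOME: 5.0,
        S.N_ADULTS: 2.0,
        S.N_CHILDREN: 0.0,
        S.BMI: 27.0,
        S.PREGNANT: 0.0,
        S.WEIGHT: 1.0,
    }
    data = {}
    for col in S.MICRODATA_COLUMNS:
        v = columns.get(col, defaults[col])
        v = np.atleast_1d(v)
        data[col] = np.resize(v, n) if col != S.STATE else np.resize(np.asarray(v, dtype=object), n)
    return pd.DataFrame(data)


@pytest.fixture(scope="session")
def guidelines() -> PovertyGuidelineTable:
    return load_poverty_guidelines()


@pytest.fixture(scope="session")
def toy_guidelines() -> PovertyGuidelineTable:
    return PovertyGuidelineTable(
        year=2016,
        base_dollars={"contiguous_and_DC": 10000, "alaska": 12000, "hawaii": 11000},
        increment_dollars={"contiguous_and_DC": 5000, "alaska": 6000, "hawaii": 5500},
    )


@pytest.fixture(scope="session")
def fixture_table() -> pd.DataFrame:
    return load_table2_fixture()


@pytest.fixture(scope="session")
def default_population_50k() -> pd.DataFrame:
    """One-state draw at n=50,000 under the default (survey-like) margins."""
    cfg = GeneratorConfig(states=("Texas",), n_per_state=50_000, seed=11)
    return generate_population(cfg)
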