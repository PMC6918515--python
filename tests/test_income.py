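import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hwdi import _schema as S
from hwdi.income import (
    INCOME_CATEGORY_TOP_DOLLARS,
    IncomeValidationError,
    PovertyGuidelineTable,
    add_income_classification,
    assign_income_dollars,
    classify_hwdi_groups,
    classify_rhwdi_groups,
    percentile_75,
    poverty_ratio,
    region_for_state,
)

from conftest import make_records


def reference_p75(values):
    """Independent brute-force 75th percentile: h = 0.75*n; average the h-th
    and (h+1)-th order statistics when h is an integer, else take the
    ceil(h)-th (1-based)."""
    xs = sorted(values)
    n = len(xs)
    h = 0.75 * n
    if abs(h - round(h)) < 1e-12:
        k = int(round(h))
        return (xs[k - 1] + xs[k]) / 2 if k < n else xs[-1]
    import math

    return xs[math.ceil(h) - 1]


class TestAssignIncomeDollars:
    def test_full_mapping(self):
        assert [assign_income_dollars(c) for c in range(1, 9)] == list(
            map(float, INCOME_CATEGORY_TOP_DOLLARS)
        )

    def test_lowest_category(self):
        assert assign_income_dollars(1) == 9999

    def test_capped_top_category(self):
        assert assign_income_dollars(8) == 75000

    def test_category_5_top_of_range(self):
        assert assign_income_dollars(5) == 34999

    @pytest.mark.parametrize("bad", [0, 9, 2.5, -1])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(IncomeValidationError):
            assign_income_dollars(bad)

    def test_nan_propagates(self):
        out = assign_income_dollars([1.0, np.nan, 8.0])
        assert out[0] == 9999 and np.isnan(out[1]) and out[2] == 75000


class TestPovertyRatio:
    def test_ratio_identity(self, toy_guidelines):
        g = toy_guidelines.guideline("contiguous_and_DC", 2)
        assert poverty_ratio(g, 2, "Texas", toy_guidelines) == pytest.approx(100.0)

    def test_arithmetic_example(self, toy_guidelines):
        # base 10,000 / increment 5,000, household of 3 -> guideline 20,000.
        assert poverty_ratio(37_000, 3, "Texas", toy_guidelines) == pytest.approx(185.0)

    def test_larger_base_smaller_ratio(self, toy_guidelines):
        r_contig = poverty_ratio(30_000, 2, "Texas", toy_guidelines)
        r_alaska = poverty_ratio(30_000, 2, "Alaska", toy_guidelines)
        assert r_alaska < r_contig

    def test_monotone_in_income_and_size(self, toy_guidelines):
        assert poverty_ratio(40_000, 2, "Ohio", toy_guidelines) > poverty_ratio(
            30_000, 2, "Ohio", toy_guidelines
        )
        assert poverty_ratio(30_000, 3, "Ohio", toy_guidelines) < poverty_ratio(
            30_000, 2, "Ohio", toy_guidelines
        )

    def test_household_size_below_one_rejected(self, toy_guidelines):
        with pytest.raises(IncomeValidationError):
            poverty_ratio(30_000, 0, "Ohio", toy_guidelines)

    def test_region_mapping(self):
        assert region_for_state("Alaska") == "alaska"
        assert region_for_state("HI") == "hawaii"
        assert region_for_state("District of Columbia") == "contiguous_and_DC"

    def test_guideline_strictly_increasing_in_size(self, guidelines):
        sizes = np.arange(1, 10)
        for region in ("contiguous_and_DC", "alaska", "hawaii"):
            g = guidelines.guideline(region, sizes)
            assert np.all(np.diff(g) > 0)

    def test_invalid_guideline_table_rejected(self):
        with pytest.raises(IncomeValidationError):
            PovertyGuidelineTable(
                year=2016,
                base_dollars={"contiguous_and_DC": -1, "alaska": 1, "hawaii": 1},
                increment_dollars={"contiguous_and_DC": 1, "alaska": 1, "hawaii": 1},
            )


class TestHwdiGroups:
    @pytest.mark.parametrize(
        "cat,group",
        [(1, "low"), (5, "low"), (6, "middle"), (7, "middle"), (8, "high")],
    )
    def test_fixed_dollar_boundaries(self, cat, group):
        assert classify_hwdi_groups(cat) == group

    def test_out_of_range(self):
        with pytest.raises(IncomeValidationError):
            classify_hwdi_groups(9)


class TestRhwdiGroups:
    def test_185_boundary_is_low(self):
        labels = classify_rhwdi_groups([185.0, 186.0, 400.0, 500.0])
        assert labels[0] == "low" and labels[1] == "middle"

    def test_documented_example(self):
        # p75 of {100, 200, 300, 400} = 350 under the averaged-inverted-CDF
        # definition -> groups low, middle, middle, high.
        assert percentile_75([100, 200, 300, 400]) == pytest.approx(350.0)
        labels = classify_rhwdi_groups([100.0, 200.0, 300.0, 400.0])
        assert list(labels) == ["low", "middle", "middle", "high"]

    def test_degenerate_all_equal_above_185(self, caplog):
        labels = classify_rhwdi_groups([250.0] * 6)
        assert list(labels) == ["middle"] * 6  # p75 == 250, boundary is <=

    def test_degenerate_p75_below_185_warns(self, caplog):
        with caplog.at_level("WARNING", logger="hwdi.income"):
            labels = classify_rhwdi_groups([100.0, 120.0, 150.0, 180.0])
        assert "degenerate" in caplog.text
        assert "middle" not in set(labels)

    def test_all_missing_rejected(self):
        with pytest.raises(IncomeValidationError):
            classify_rhwdi_groups([np.nan, np.nan])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        ratios = rng.uniform(50, 600, 40)
        perm = rng.permutation(40)
        a = classify_rhwdi_groups(ratios)
        b = classify_rhwdi_groups(ratios[perm])
        assert list(np.asarray(a)[perm]) == list(b)

    @given(
        st.lists(st.floats(min_value=1, max_value=1e4, allow_nan=False), min_size=1, max_size=10)
    )
    @settings(max_examples=200, deadline=None)
    def test_p75_matches_brute_force_oracle(self, values):
        assert percentile_75(values) == pytest.approx(reference_p75(values))

    def test_weighted_percentile_reduces_to_unweighted(self):
        vals = [100.0, 200.0, 300.0, 400.0, 500.0]
        assert percentile_75(vals, weights=[1] * 5) == pytest.approx(reference_p75(vals))


class TestAddIncomeClassification:
    def test_partition_every_complete_record_labeled(self, guidelines):
        rng = np.random.default_rng(1)
        n = 300
        df = make_records(
            n=n,
            state=rng.choice(["Texas", "Alaska", "Hawaii"], n),
            income_category=rng.choice(S.INCOME_LEVELS, n).astype(float),
            n_adults=rng.choice([1, 2, 3], n).astype(float),
            n_children=rng.choice([0, 1, 2], n).astype(float),
        )
        out = add_income_classification(df, guidelines)
        assert out[S.HWDI_GROUP].isin(S.GROUPS).all()
        assert out[S.RHWDI_GROUP].isin(S.GROUPS).all()
        assert (out[S.POVERTY_RATIO] > 0).all()

    def test_assigned_income_is_category_top(self, guidelines):
        df = make_records(n=8, income_category=[float(c) for c in range(1, 9)])
        out = add_income_classification(df, guidelines)
        assert list(out[S.ASSIGNED_INCOME]) == list(map(float, INCOME_CATEGORY_TOP_DOLLARS))

    def test_alaska_hawaii_use_their_own_guidelines(self, guidelines):
        df = make_records(n=3, state=["Texas", "Alaska", "Hawaii"], income_category=5.0, n_adults=2.0)
        out = add_income_classification(df, guidelines).set_index(S.STATE)
        assert out.loc["Alaska", S.POVERTY_RATIO] < out.loc["Hawaii", S.POVERTY_RATIO]
        assert out.loc["Hawaii", S.POVERTY_RATIO] < out.loc["Texas", S.POVERTY_RATIO]

    def test_missing_income_leaves_labels_missing(self, guidelines):
        df = make_records(n=3, income_category=[2.0, np.nan, 8.0])
        out = add_income_classification(df, guidelines)
        assert out[S.HWDI_GROUP].isna()[1]
        assert out[S.RHWDI_GROUP].isna()[1]
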