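"""Range, frequency and inferred-distribution valuation primitives."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ranksat import (
    ContextSet,
    DegenerateContextError,
    fit_parametric,
    frequency_value,
    inferred_rank,
    mean_inferred_rank,
    ordinal_rank,
    range_value,
    rft_value,
    sample_relative_rank,
)
from conftest import brute_force_relative_rank


class TestRangeValue:
    @pytest.mark.parametrize(
        "x, lo, hi, expected",
        [
            (20, 10, 30, 0.5),  # worked range-principle values
            (20, 15, 40, 0.2),
            (10, 10, 30, 0.0),  # lower endpoint
            (30, 10, 30, 1.0),
        ],
    )
    def test_worked_values(self, x, lo, hi, expected):
        assert range_value(x, ContextSet([lo, hi])) == pytest.approx(expected)

    def test_out_of_range_values_clamp(self):
        ctx = ContextSet([10, 30])
        assert range_value(5, ctx) == 0.0
        assert range_value(99, ctx) == 1.0

    def test_degenerate_context_rejected(self):
        with pytest.raises(DegenerateContextError):
            ContextSet([7, 7, 7])


class TestOrdinalAndFrequency:
    @pytest.mark.parametrize(
        "x, column, expected_rank",
        [
            (23, "unimodal", 2),
            (23, "bimodal", 5),
            (49, "unimodal", 10),
            (49, "bimodal", 7),
            (9, "unimodal", 1),
        ],
    )
    def test_critical_point_ranks(self, x, column, expected_rank, all_exp1_columns):
        assert ordinal_rank(x, all_exp1_columns[column]) == expected_rank

    def test_nonmember_rejected(self, unimodal):
        with pytest.raises(ValueError):
            ordinal_rank(24.5, unimodal)

    def test_ties_share_average_rank(self):
        ctx = ContextSet([1, 2, 2, 5])
        assert ordinal_rank(2, ctx) == pytest.approx(2.5)

    @pytest.mark.parametrize(
        "x, expected",
        [(23, 0.1), (49, 0.9), (9, 0.0), (63, 1.0)],
    )
    def test_unimodal_frequency_values(self, x, expected, unimodal):
        assert frequency_value(x, unimodal) == pytest.approx(expected)

    def test_matches_pair_counting_oracle_on_all_small_subsets(self, all_exp1_columns):
        """Frequency value equals the brute-force pairwise-comparison oracle
        on every subset of size 2..8 of each stimulus column."""
        for ctx in all_exp1_columns.values():
            vals = ctx.values
            for k in range(2, 9):
                for subset in itertools.combinations(vals, k):
                    sub_ctx = ContextSet(subset)
                    for x in subset:
                        assert frequency_value(x, sub_ctx) == pytest.approx(
                            brute_force_relative_rank(x, subset)
                        )


class TestRFTValue:
    def test_limit_cases(self, unimodal):
        for x in (23, 36, 49):
            assert rft_value(x, unimodal, 1.0) == pytest.approx(range_value(x, unimodal))
            assert rft_value(x, unimodal, 0.0) == pytest.approx(
                frequency_value(x, unimodal)
            )

    def test_hand_computed_blend(self, unimodal):
        # 23 in the unimodal column: range (23-9)/54, frequency .1
        expected = 0.5 * (14 / 54) + 0.5 * 0.1
        assert rft_value(23, unimodal, 0.5) == pytest.approx(expected)

    def test_monotone_in_x(self, all_exp1_columns):
        for ctx in all_exp1_columns.values():
            for w in (0.0, 0.3, 0.7, 1.0):
                vals = [rft_value(x, ctx, w) for x in ctx.values]
                assert all(b >= a for a, b in zip(vals, vals[1:]))

    @given(w=st.floats(0, 1), i=st.integers(0, 10))
    @settings(max_examples=60, deadline=None)
    def test_stays_in_unit_interval(self, w, i, unimodal):
        assert 0.0 <= rft_value(unimodal.values[i], unimodal, w) <= 1.0

    def test_invalid_weight_rejected(self, unimodal):
        with pytest.raises(ValueError):
            rft_value(23, unimodal, 1.5)


class TestSampleRelativeRank:
    def test_dbs_worked_example(self):
        # 15-day feedback against a mental sample of 5 shorter, 2 longer
        sample = [3, 5, 8, 10, 12, 20, 30]
        assert sample_relative_rank(15, sample) == pytest.approx(5 / 7)

    def test_extremes_and_ties(self):
        assert sample_relative_rank(1, [2, 3, 4]) == 0.0
        assert sample_relative_rank(5, [3, 5, 7]) == pytest.approx(0.5)

    def test_orientation_flip(self):
        # for a higher-is-better magnitude, "better" items are the larger ones
        assert sample_relative_rank(15, [3, 5, 8, 10, 12, 20, 30],
                                    "higher_is_better") == pytest.approx(2 / 7)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            sample_relative_rank(1, [])

    @given(st.lists(st.integers(0, 50), min_size=1, max_size=12),
           st.integers(0, 50))
    @settings(max_examples=100, deadline=None)
    def test_unit_interval_and_pair_count(self, sample, x):
        r = sample_relative_rank(x, sample)
        assert 0.0 <= r <= 1.0
        wins = sum(1.0 if v < x else 0.5 if v == x else 0.0 for v in sample)
        assert r == pytest.approx(wins / len(sample))


class TestParametricFits:
    def test_normal_fit_matches_worked_heights(self):
        belief = fit_parametric([138, 140, 155], "normal")
        assert belief.location == pytest.approx(144.3333, abs=1e-3)
        assert belief.scale == pytest.approx(9.2916, abs=1e-3)
        # paper-level rounding
        assert round(belief.location) == 144
        assert round(belief.scale, 1) == 9.3

    def test_lognormal_fit_on_negatively_skewed_column(self, neg_skew):
        belief = fit_parametric(neg_skew.values, "lognormal")
        logs = np.log(neg_skew.values)
        assert belief.location == pytest.approx(logs.mean())
        assert belief.scale == pytest.approx(logs.std(ddof=0))
        assert belief.location == pytest.approx(3.732, abs=1e-3)
        assert belief.scale == pytest.approx(0.549, abs=1e-3)

    def test_uniform_fit_recovers_endpoints(self):
        belief = fit_parametric([0, 10, 0, 10, 0, 10], "uniform")
        assert belief.location == pytest.approx(0.0, abs=1e-9)
        assert belief.scale == pytest.approx(10.0, abs=1e-9)

    def test_degenerate_and_nonpositive_rejected(self):
        with pytest.raises(DegenerateContextError):
            fit_parametric([4, 4, 4], "normal")
        with pytest.raises(ValueError):
            fit_parametric([-1, 2, 3], "lognormal")


class TestInferredRank:
    def test_height_worked_example(self):
        belief = fit_parametric([138, 140, 155], "normal")
        assert round(inferred_rank(140, belief), 2) == 0.32

    def test_median_maps_to_half(self):
        for family, values in [
            ("normal", [138, 140, 155]),
            ("lognormal", [9, 26, 36, 43]),
            ("uniform", [0, 5, 10]),
        ]:
            belief = fit_parametric(values, family)
            assert inferred_rank(belief.median, belief) == pytest.approx(0.5, abs=1e-9)

    def test_uniform_linear_cdf(self):
        belief = fit_parametric([0, 10], "uniform")
        assert inferred_rank(2.5, belief) == pytest.approx(0.25)

    @pytest.mark.parametrize(
        "column, expected",
        [("neg_skew", 0.55), ("pos_skew", 0.48)],
    )
    def test_mean_inferred_lognormal_rank_of_skewed_columns(
        self, column, expected, all_exp1_columns
    ):
        assert round(
            mean_inferred_rank(all_exp1_columns[column], "lognormal"), 2
        ) == expected

    def test_uniform_family_on_evenly_spaced_values_matches_empirical(self):
        values = list(range(0, 55, 5))
        ctx = ContextSet(values)
        empirical = np.mean([frequency_value(v, ctx) for v in values])
        assert mean_inferred_rank(ctx, "uniform") == pytest.approx(empirical, abs=1e-9)
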