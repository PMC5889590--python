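"""Time-forward gap engine: worked examples, oracle agreement, invariants."""

from __future__ import annotations

from datetime import timedelta
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medgap.claims import Indication
from medgap.cmg import (
    AdherenceClass,
    FewerThanTwoFillsError,
    LookbackWindow,
    NonCalculableReason,
    classify_adherence,
    compute_indication_cmg,
    daily_inventory_oracle,
    select_window_fills,
    time_forward_gaps,
)

from conftest import day, dispensing, eligible, fills, random_fill_series


class TestTimeForwardGaps:
    @pytest.mark.parametrize(
        "series, expected_gap, expected_observed",
        [
            # perfect refill timing: no uncovered days
            (fills((0, 30), (30, 30)), 0, 30),
            # two 10-day delays, never recovered
            (fills((0, 30), (40, 30), (80, 30)), 20, 80),
            # stockpile carries forward: 30 surplus from interval 1 covers
            # most of the long second interval
            (fills((0, 60), (30, 30), (100, 10)), 10, 100),
            # a later large fill must NOT retroactively erase the early gap
            (fills((0, 10), (40, 60), (60, 40)), 30, 60),
        ],
    )
    def test_worked_examples(self, series, expected_gap, expected_observed):
        gap, observed, trace = time_forward_gaps(series)
        assert (gap, observed) == (expected_gap, expected_observed)
        assert sum(iv.gap_days for iv in trace) == gap
        assert sum(iv.length_days for iv in trace) == observed

    def test_stockpiling_trace_details(self):
        _, _, trace = time_forward_gaps(fills((0, 60), (30, 30), (100, 10)))
        assert trace[0].supply_available == 60
        assert trace[0].carryover_out == 30
        assert trace[1].supply_available == 60  # 30 carryover + 30 fill
        assert trace[1].gap_days == 10

    def test_terminal_surplus_discarded(self):
        # carryover at the final fill does not extend the observation
        gap, observed, _ = time_forward_gaps(fills((0, 10), (40, 60), (60, 40)))
        assert observed == 60 and gap == 30

    def test_fewer_than_two_fills_signals(self):
        with pytest.raises(FewerThanTwoFillsError):
            time_forward_gaps(fills((0, 30)))
        with pytest.raises(FewerThanTwoFillsError):
            daily_inventory_oracle(fills())

    def test_non_increasing_dates_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            time_forward_gaps(fills((10, 30), (10, 30)))

    @pytest.mark.parametrize(
        "series, expected",
        [
            (fills((0, 30), (30, 30)), (0, 30)),
            (fills((0, 30), (40, 30), (80, 30)), (20, 80)),
        ],
    )
    def test_oracle_worked_examples(self, series, expected):
        assert daily_inventory_oracle(series) == expected

    def test_matches_daily_inventory_on_random_series(self, rng):
        for _ in range(200):
            series = random_fill_series(rng)
            gap, observed, _ = time_forward_gaps(series)
            assert (gap, observed) == daily_inventory_oracle(series)


@st.composite
def fill_series(draw, min_fills=2, max_fills=6):
    n = draw(st.integers(min_fills, max_fills))
    spacings = draw(
        st.lists(st.integers(1, 200), min_size=n - 1, max_size=n - 1)
    )
    supplies = draw(st.lists(st.integers(1, 120), min_size=n, max_size=n))
    offsets = [0]
    for s in spacings:
        offsets.append(offsets[-1] + s)
    return [(day(o), s) for o, s in zip(offsets, supplies)]


class TestEngineProperties:
    @settings(max_examples=100, derandomize=True)
    @given(fill_series())
    def test_bounded_and_oracle_equivalent(self, series):
        gap, observed, trace = time_forward_gaps(series)
        assert (gap, observed) == daily_inventory_oracle(series)
        assert 0 <= gap <= observed
        for iv in trace:
            assert 0 <= iv.gap_days <= iv.length_days

    @settings(max_examples=100, derandomize=True)
    @given(fill_series(), st.integers(0, 5), st.integers(1, 100))
    def test_stockpile_causality(self, series, which, extra):
        """Raising fill k's supply never touches earlier intervals and never
        increases any gap at or after k."""
        k = which % len(series)
        bumped = list(series)
        bumped[k] = (bumped[k][0], bumped[k][1] + extra)
        _, _, before = time_forward_gaps(series)
        _, _, after = time_forward_gaps(bumped)
        for i, (a, b) in enumerate(zip(before, after)):
            if i < k:
                assert b.gap_days == a.gap_days
            else:
                assert b.gap_days <= a.gap_days

    @settings(max_examples=100, derandomize=True)
    @given(fill_series(), st.integers(-3000, 3000))
    def test_translation_invariance(self, series, shift):
        shifted = [(d + timedelta(days=shift), s) for d, s in series]
        gap, observed, _ = time_forward_gaps(series)
        gap2, observed2, _ = time_forward_gaps(shifted)
        assert (gap, observed) == (gap2, observed2)

    @settings(max_examples=100, derandomize=True)
    @given(fill_series())
    def test_full_coverage_means_zero_gap(self, series):
        # give every interval at least its length in supply
        padded = []
        for (d, _), nxt in zip(series, series[1:]):
            padded.append((d, (nxt[0] - d).days))
        padded.append(series[-1])
        gap, _, _ = time_forward_gaps(padded)
        assert gap == 0


class TestSelectWindowFills:
    def test_window_filter(self):
        window = LookbackWindow(day(400), window_days=365)
        records = [dispensing(offset=o) for o in (0, 300, 390)]
        kept = select_window_fills(records, window)
        assert [r.fill_date for r in kept] == [day(300), day(390)]

    def test_window_endpoints_inclusive(self):
        window = LookbackWindow(day(365), window_days=365)
        records = [dispensing(offset=0), dispensing(offset=365)]
        assert len(select_window_fills(records, window)) == 2

    def test_same_day_same_ingredient_merged(self):
        window = LookbackWindow(day(100))
        records = [dispensing(offset=50, supply=30), dispensing(offset=50, supply=30)]
        merged = select_window_fills(records, window)
        assert len(merged) == 1
        assert merged[0].days_supply == 60

    def test_same_day_different_ingredient_not_merged(self):
        window = LookbackWindow(day(100))
        records = [
            dispensing(offset=50, ingredient="metformin"),
            dispensing(offset=50, ingredient="glipizide"),
        ]
        assert len(select_window_fills(records, window)) == 2

    def test_empty_input(self):
        assert select_window_fills([], LookbackWindow(day(0))) == []


class TestClassifyAdherence:
    def test_exact_threshold_is_optimal(self):
        assert classify_adherence(Fraction(1, 5)) is AdherenceClass.OPTIMAL
        assert classify_adherence(Fraction(20, 100)) is AdherenceClass.OPTIMAL

    def test_just_over_threshold_is_suboptimal(self):
        assert classify_adherence(Fraction(21, 100)) is AdherenceClass.SUBOPTIMAL

    def test_zero_gap_is_optimal(self):
        assert classify_adherence(Fraction(0)) is AdherenceClass.OPTIMAL

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            classify_adherence(Fraction(3, 2))


class TestComputeIndicationCmg:
    def window(self):
        return LookbackWindow(day(365), window_days=365)

    def test_single_ingredient_passthrough(self):
        records = [dispensing(offset=o) for o in (100, 140, 180)]  # 10-day delays
        result, trace = compute_indication_cmg(
            records, self.window(), eligible(), "P1", Indication.DIABETES_ORAL
        )
        assert result.calculable
        assert result.cmg == Fraction(20, 80)
        assert result.adherence_class is AdherenceClass.SUBOPTIMAL
        assert len(trace) == 2

    def test_pooled_days_aggregation(self):
        # ingredient A: gap 10 / observed 100; ingredient B: gap 30 / observed 60
        a = [
            dispensing(offset=0, ingredient="A", supply=90),
            dispensing(offset=100, ingredient="A", supply=30),
        ]
        b = [
            dispensing(offset=0, ingredient="B", supply=30),
            dispensing(offset=60, ingredient="B", supply=30),
        ]
        result, _ = compute_indication_cmg(
            a + b, self.window(), eligible(), "P1", Indication.DIABETES_ORAL
        )
        assert result.cmg == Fraction(40, 160)
        assert result.adherence_class is AdherenceClass.SUBOPTIMAL

    def test_mean_per_ingredient_aggregation(self):
        a = [
            dispensing(offset=0, ingredient="A", supply=90),
            dispensing(offset=100, ingredient="A", supply=30),
        ]
        b = [
            dispensing(offset=0, ingredient="B", supply=30),
            dispensing(offset=60, ingredient="B", supply=30),
        ]
        result, _ = compute_indication_cmg(
            a + b,
            self.window(),
            eligible(),
            "P1",
            Indication.DIABETES_ORAL,
            aggregation="mean_per_ingredient",
        )
        assert result.cmg == (Fraction(10, 100) + Fraction(30, 60)) / 2

    def test_single_fill_not_calculable(self):
        result, _ = compute_indication_cmg(
            [dispensing(offset=100)], self.window(), eligible(), "P1",
            Indication.DIABETES_ORAL,
        )
        assert not result.calculable
        assert result.non_calculable_reason is NonCalculableReason.FEWER_THAN_TWO_FILLS
        assert result.adherence_class is AdherenceClass.NOT_APPLICABLE

    def test_ingredient_switch_does_not_pool_single_fills(self):
        # one fill of each of two drugs: no ingredient completes an interval
        records = [
            dispensing(offset=100, ingredient="A"),
            dispensing(offset=200, ingredient="B"),
        ]
        result, _ = compute_indication_cmg(
            records, self.window(), eligible(), "P1", Indication.DIABETES_ORAL
        )
        assert result.non_calculable_reason is NonCalculableReason.FEWER_THAN_TWO_FILLS

    def test_gate_precedence(self):
        records = [dispensing(offset=o) for o in (100, 140)]
        dual_and_no_benefits = eligible(continuous=False, dual=True)
        result, _ = compute_indication_cmg(
            records, self.window(), dual_and_no_benefits, "P1",
            Indication.DIABETES_ORAL,
        )
        assert result.non_calculable_reason is NonCalculableReason.DUAL_COVERAGE

        result, _ = compute_indication_cmg(
            records, self.window(), eligible(continuous=False), "P1",
            Indication.DIABETES_ORAL,
        )
        assert result.non_calculable_reason is NonCalculableReason.NO_CONTINUOUS_BENEFITS

    def test_insulin_excluded(self):
        result, _ = compute_indication_cmg(
            [], self.window(), eligible(), "P1", Indication.INSULIN
        )
        assert result.non_calculable_reason is NonCalculableReason.INSULIN_EXCLUDED
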