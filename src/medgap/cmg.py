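"""Continuous Medication Gap (CMG) over a 12-month lookback.

CMG is a secondary-adherence measure: the proportion of days between a
patient's first and last fill (within the lookback window) on which no
medication supply was available.  Each refill interval — the span between
two consecutive fills — contributes its uncovered days; interval gaps are
summed and divided by the total observed days.

Naive gap accounting mishandles stockpiling: a patient who refills early
accumulates surplus pills, and if that surplus is allowed to offset past
intervals the measure understates true gaps.  The engine therefore uses a
time-forward algorithm: supply left over at the end of an interval carries
forward into future intervals, but a later fill can never retroactively
erase a gap already incurred.

Gap accounting is exact integer arithmetic and the CMG itself an exact
rational (``fractions.Fraction``), so the optimal-adherence comparison at
the 20% threshold has no floating-point ambiguity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date, timedelta
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from medgap.claims import DispensingRecord, Indication, PatientEligibility

#: CMG at or below this bound classifies as optimal adherence
#: (medication available >= 80% of observed days).
OPTIMAL_THRESHOLD = Fraction(1, 5)


class NonCalculableReason(str, enum.Enum):
    """Why a patient × indication CMG could not be computed."""

    FEWER_THAN_TWO_FILLS = "fewer_than_two_fills"
    DUAL_COVERAGE = "dual_coverage"
    NO_CONTINUOUS_BENEFITS = "no_continuous_benefits"
    INSULIN_EXCLUDED = "insulin_excluded"
    NONE = "none"


class AdherenceClass(str, enum.Enum):
    OPTIMAL = "optimal"
    SUBOPTIMAL = "suboptimal"
    NOT_APPLICABLE = "not_applicable"


class FewerThanTwoFillsError(ValueError):
    """At least two fills are required to form a refill interval."""


@dataclass(frozen=True)
class LookbackWindow:
    """Claims lookback anchored at the adherence-assessment (index) date.

    Spans ``[index_date - window_days, index_date]``, both endpoints
    inclusive.
    """

    index_date: date
    window_days: int = 365

    @property
    def start(self) -> date:
        return self.index_date - timedelta(days=self.window_days)

    def __contains__(self, day: date) -> bool:
        return self.start <= day <= self.index_date


@dataclass(frozen=True)
class RefillInterval:
    """One span between consecutive fills, with its supply accounting.

    ``supply_available`` is the carryover entering the interval plus the
    days-supply dispensed at ``start_date``; uncovered days are
    ``max(0, length - supply)`` and surplus carries out to the next interval.
    """

    start_date: date
    end_date: date
    length_days: int
    supply_available: int
    gap_days: int
    carryover_out: int

    def __post_init__(self) -> None:
        if self.length_days <= 0:
            raise ValueError("interval length must be positive")
        if self.gap_days != max(0, self.length_days - self.supply_available):
            raise ValueError("gap_days inconsistent with length and supply")
        if self.carryover_out != max(0, self.supply_available - self.length_days):
            raise ValueError("carryover_out inconsistent with length and supply")


@dataclass(frozen=True)
class CmgResult:
    """Per patient × indication gap summary and adherence classification."""

    patient_id: str
    indication: Indication
    observed_days: int
    gap_days: int
    cmg: Fraction | None
    calculable: bool
    non_calculable_reason: NonCalculableReason
    adherence_class: AdherenceClass

    def __post_init__(self) -> None:
        if self.calculable != (self.non_calculable_reason is NonCalculableReason.NONE):
            raise ValueError("calculable flag inconsistent with reason")
        if self.calculable:
            if self.cmg is None or not 0 <= self.cmg <= 1:
                raise ValueError(f"calculable CMG must lie in [0, 1], got {self.cmg}")
            if self.adherence_class is AdherenceClass.NOT_APPLICABLE:
                raise ValueError("calculable CMG must be classified")


def select_window_fills(
    fills: Iterable[DispensingRecord], window: LookbackWindow
) -> list[DispensingRecord]:
    """Keep fills inside the window, sorted by date, merging same-day fills.

    Same-day fills of the same ingredient are merged by summing days_supply
    (a split dispensing is one supply event).  All fills must belong to one
    patient and one indication.
    """
    inside = [f for f in fills if f.fill_date in window]
    merged: dict[tuple[date, str], DispensingRecord] = {}
    for f in sorted(inside, key=lambda r: (r.fill_date, r.ingredient)):
        key = (f.fill_date, f.ingredient)
        if key in merged:
            prev = merged[key]
            merged[key] = DispensingRecord(
                patient_id=prev.patient_id,
                fill_date=prev.fill_date,
                ingredient=prev.ingredient,
                indication=prev.indication,
                days_supply=prev.days_supply + f.days_supply,
            )
        else:
            merged[key] = f
    return sorted(merged.values(), key=lambda r: (r.fill_date, r.ingredient))


def time_forward_gaps(
    fills: Sequence[tuple[date, int]],
) -> tuple[int, int, list[RefillInterval]]:
    """Interval-arithmetic gap accounting for one ingredient's fill series.

    ``fills`` are (fill_date, days_supply) pairs with strictly increasing
    dates.  Observation runs from the first to the last fill date; surplus
    supply at the final fill is discarded because no further interval is
    observed.  Returns (gap_days, observed_days, interval trace).
    """
    if len(fills) < 2:
        raise FewerThanTwoFillsError(
            f"need at least 2 fills to form a refill interval, got {len(fills)}"
        )
    dates = [d for d, _ in fills]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("fill dates must be strictly increasing")

    trace: list[RefillInterval] = []
    carry = 0
    gap_total = 0
    observed = 0
    for (start, supply), (end, _) in zip(fills, fills[1:]):
        length = (end - start).days
        available = carry + supply
        gap = max(0, length - available)
        carry = max(0, available - length)
        trace.append(
            RefillInterval(
                start_date=start,
                end_date=end,
                length_days=length,
                supply_available=available,
                gap_days=gap,
                carryover_out=carry,
            )
        )
        gap_total += gap
        observed += length
    return gap_total, observed, trace


def daily_inventory_oracle(fills: Sequence[tuple[date, int]]) -> tuple[int, int]:
    """Day-by-day pill-inventory simulation; reference for time_forward_gaps.

    Walks one day at a time from the first fill date up to (not including)
    the last: each fill adds its supply to the inventory on its date; each
    day consumes one pill if any is on hand, else counts a gap day.  Must
    agree with the interval arithmetic on every input.
    """
    if len(fills) < 2:
        raise FewerThanTwoFillsError(
            f"need at least 2 fills to form a refill interval, got {len(fills)}"
        )
    supply_on: dict[date, int] = {}
    for d, s in fills:
        supply_on[d] = supply_on.get(d, 0) + s
    first, last = fills[0][0], fills[-1][0]
    inventory = 0
    gap_days = 0
    day = first
    while day < last:
        inventory += supply_on.get(day, 0)
        if inventory > 0:
            inventory -= 1
        else:
            gap_days += 1
        day += timedelta(days=1)
    return gap_days, (last - first).days


def classify_adherence(
    cmg: Fraction, threshold: Fraction = OPTIMAL_THRESHOLD
) -> AdherenceClass:
    """Classify a CMG value: optimal iff cmg <= threshold (default 20%).

    The comparison is on the exact rational, so a CMG of exactly 1/5 is
    optimal with no tolerance involved.
    """
    if not 0 <= cmg <= 1:
        raise ValueError(f"CMG must lie in [0, 1], got {cmg}")
    return AdherenceClass.OPTIMAL if cmg <= threshold else AdherenceClass.SUBOPTIMAL


def _non_calculable(
    patient_id: str, indication: Indication, reason: NonCalculableReason
) -> CmgResult:
    return CmgResult(
        patient_id=patient_id,
        indication=indication,
        observed_days=0,
        gap_days=0,
        cmg=None,
        calculable=False,
        non_calculable_reason=reason,
        adherence_class=AdherenceClass.NOT_APPLICABLE,
    )


def compute_indication_cmg(
    fills: Iterable[DispensingRecord],
    window: LookbackWindow,
    eligibility: PatientEligibility,
    patient_id: str,
    indication: Indication,
    threshold: Fraction = OPTIMAL_THRESHOLD,
    aggregation: str = "pooled_days",
) -> tuple[CmgResult, list[RefillInterval]]:
    """Compute one patient's CMG for one therapeutic indication.

    Calculability gates apply in fixed precedence — insulin exclusion, dual
    coverage, missing continuous benefits, then fewer than two fills — so
    non-calculable tallies are reproducible.  Gaps are computed per
    ingredient (drug switching within a class does not transfer supply
    across drugs) for every ingredient with at least two windowed fills,
    then aggregated to an indication-level CMG:

    - ``pooled_days`` (default): sum gap days over ingredients / sum
      observed days, a true day proportion weighting drugs by observed time;
    - ``mean_per_ingredient``: unweighted mean of per-ingredient CMGs.

    Returns the result plus the full interval trace for audit.
    """
    if indication is Indication.INSULIN:
        return _non_calculable(patient_id, indication, NonCalculableReason.INSULIN_EXCLUDED), []
    if eligibility.dual_coverage:
        return _non_calculable(patient_id, indication, NonCalculableReason.DUAL_COVERAGE), []
    if not eligibility.continuous_benefits:
        return (
            _non_calculable(patient_id, indication, NonCalculableReason.NO_CONTINUOUS_BENEFITS),
            [],
        )

    windowed = select_window_fills(fills, window)
    by_ingredient: dict[str, list[tuple[date, int]]] = {}
    for f in windowed:
        by_ingredient.setdefault(f.ingredient, []).append((f.fill_date, f.days_supply))

    per_ingredient: list[tuple[int, int]] = []
    trace: list[RefillInterval] = []
    for ingredient in sorted(by_ingredient):
        series = by_ingredient[ingredient]
        if len(series) < 2:
            continue
        gap, observed, ingredient_trace = time_forward_gaps(series)
        per_ingredient.append((gap, observed))
        trace.extend(ingredient_trace)

    if not per_ingredient:
        return (
            _non_calculable(patient_id, indication, NonCalculableReason.FEWER_THAN_TWO_FILLS),
            [],
        )

    gap_days = sum(g for g, _ in per_ingredient)
    observed_days = sum(o for _, o in per_ingredient)
    if aggregation == "pooled_days":
        cmg = Fraction(gap_days, observed_days)
    elif aggregation == "mean_per_ingredient":
        cmg = sum(
            (Fraction(g, o) for g, o in per_ingredient), start=Fraction(0)
        ) / len(per_ingredient)
    else:
        raise ValueError(f"unknown aggregation mode {aggregation!r}")

    result = CmgResult(
        patient_id=patient_id,
        indication=indication,
        observed_days=observed_days,
        gap_days=gap_days,
        cmg=cmg,
        calculable=True,
        non_calculable_reason=NonCalculableReason.NONE,
        adherence_class=classify_adherence(cmg, threshold),
    )
    return result, trace


def compute_cohort_cmg(
    records: Iterable[DispensingRecord],
    eligibility: Mapping[str, PatientEligibility],
    windows: Mapping[tuple[str, Indication], LookbackWindow],
    threshold: Fraction = OPTIMAL_THRESHOLD,
    aggregation: str = "pooled_days",
) -> tuple[list[CmgResult], dict[tuple[str, Indication], list[RefillInterval]]]:
    """Compute CMG for every (patient, indication) with an anchoring window.

    ``windows`` maps each (patient_id, indication) to its lookback window
    (typically anchored at that patient's selected self-report date).  Keys
    without any fills still yield a result (fewer_than_two_fills) so the
    downstream contingency tables can count respondents without claims.
    """
    by_key: dict[tuple[str, Indication], list[DispensingRecord]] = {}
    for r in records:
        by_key.setdefault((r.patient_id, r.indication), []).append(r)

    results: list[CmgResult] = []
    traces: dict[tuple[str, Indication], list[RefillInterval]] = {}
    for (patient_id, indication), window in sorted(
        windows.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        elig = eligibility.get(patient_id)
        if elig is None:
            raise KeyError(f"patient {patient_id!r} missing from eligibility table")
        fills = by_key.get((patient_id, indication), [])
        result, trace = compute_indication_cmg(
            fills, window, elig, patient_id, indication, threshold, aggregation
        )
        results.append(result)
        traces[(patient_id, indication)] = trace
    return results, traces
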