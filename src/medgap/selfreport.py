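"""Selection, categorization and cross-mode pairing of 7-day recall responses.

Patients answer "in the last 7 days, how many days did you miss taking
your ... pill" (0–7) through two modes: automated telephone self-management
(ATSM) calls and a structured interview.  For analysis one response is
selected per patient × indication × source (the first completed by default;
the last as a sensitivity alternative), responses are categorized into
0 / 1 / 2–7 missed days, and ATSM responses are paired with interview
responses falling within a 30-day window for concordance analysis.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Literal

from medgap.claims import Indication, SelfReportResponse, Source

logger = logging.getLogger(__name__)


class MissedDayCategory(str, enum.Enum):
    """Three-level grouping of 7-day missed-pill counts."""

    ZERO = "zero"
    ONE = "one"
    TWO_TO_SEVEN = "two_to_seven"


CATEGORY_ORDER = (
    MissedDayCategory.ZERO,
    MissedDayCategory.ONE,
    MissedDayCategory.TWO_TO_SEVEN,
)


@dataclass(frozen=True)
class ConcordancePair:
    """Matched ATSM and interview answers for one patient × indication."""

    patient_id: str
    indication: Indication
    atsm_missed: int
    interview_missed: int
    atsm_date: date
    interview_date: date


def select_response(
    responses: Iterable[SelfReportResponse],
    mode: Literal["first", "last"] = "first",
) -> SelfReportResponse | None:
    """Pick the analyzable response from one patient+indication+source group.

    ``first`` keeps the earliest response date, ``last`` the latest.  Two
    responses on the same date tie-break deterministically on the lower
    missed-days count (conservative toward adherence) with a logged warning.
    Empty input yields ``None``.
    """
    if mode not in ("first", "last"):
        raise ValueError(f"mode must be 'first' or 'last', got {mode!r}")
    pool = list(responses)
    if not pool:
        return None
    if mode == "first":
        target = min(r.response_date for r in pool)
    else:
        target = max(r.response_date for r in pool)
    on_date = [r for r in pool if r.response_date == target]
    if len(on_date) > 1:
        logger.warning(
            "patient %s %s/%s: %d responses on %s; keeping lowest missed_days",
            on_date[0].patient_id,
            on_date[0].source.value,
            on_date[0].indication.value,
            len(on_date),
            target,
        )
    return min(on_date, key=lambda r: r.missed_days)


def select_all_responses(
    responses: Iterable[SelfReportResponse],
    mode: Literal["first", "last"] = "first",
) -> dict[tuple[str, Source, Indication], SelfReportResponse]:
    """Apply :func:`select_response` per patient × source × indication."""
    groups: dict[tuple[str, Source, Indication], list[SelfReportResponse]] = {}
    for r in responses:
        groups.setdefault((r.patient_id, r.source, r.indication), []).append(r)
    out = {}
    for key in sorted(groups, key=lambda k: (k[0], k[1].value, k[2].value)):
        chosen = select_response(groups[key], mode)
        if chosen is not None:
            out[key] = chosen
    return out


def categorize_missed_days(missed_days: int) -> MissedDayCategory:
    """Map a 0–7 missed-day count to its category; total on exactly 0–7."""
    if missed_days == 0:
        return MissedDayCategory.ZERO
    if missed_days == 1:
        return MissedDayCategory.ONE
    if 2 <= missed_days <= 7:
        return MissedDayCategory.TWO_TO_SEVEN
    raise ValueError(f"missed_days must be in [0, 7], got {missed_days}")


def pair_for_concordance(
    atsm_selections: Iterable[SelfReportResponse],
    interview_selections: Iterable[SelfReportResponse],
    window_days: int = 30,
) -> tuple[list[ConcordancePair], dict[str, int]]:
    """Match ATSM with interview selections per patient × indication.

    A pair is emitted iff both sources selected a response for the patient
    and indication and the absolute difference between the two response
    dates is at most ``window_days`` (symmetric window: the rule does not
    privilege either direction).  Unpaired selections are tallied by reason.
    """
    if window_days < 0:
        raise ValueError("window_days must be non-negative")
    atsm = {(r.patient_id, r.indication): r for r in atsm_selections}
    interview = {(r.patient_id, r.indication): r for r in interview_selections}
    for r in atsm.values():
        if r.source is not Source.ATSM:
            raise ValueError(f"non-ATSM response in atsm_selections: {r}")
    for r in interview.values():
        if r.source is not Source.INTERVIEW:
            raise ValueError(f"non-interview response in interview_selections: {r}")

    pairs: list[ConcordancePair] = []
    tally = {"missing_source": 0, "outside_window": 0}
    for key in sorted(
        set(atsm) | set(interview), key=lambda k: (k[0], k[1].value)
    ):
        a, i = atsm.get(key), interview.get(key)
        if a is None or i is None:
            tally["missing_source"] += 1
            continue
        if abs((a.response_date - i.response_date).days) > window_days:
            tally["outside_window"] += 1
            continue
        pairs.append(
            ConcordancePair(
                patient_id=key[0],
                indication=key[1],
                atsm_missed=a.missed_days,
                interview_missed=i.missed_days,
                atsm_date=a.response_date,
                interview_date=i.response_date,
            )
        )
    return pairs, tally
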