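"""Shared fixtures and helpers for the medgap test suite."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest

from medgap.claims import (
    DispensingRecord,
    Indication,
    PatientEligibility,
    SelfReportResponse,
    Source,
)

EPOCH = date(2010, 1, 1)


def day(n: int) -> date:
    """Calendar date n days after the test epoch."""
    return EPOCH + timedelta(days=int(n))


def fills(*pairs: tuple[int, int]) -> list[tuple[date, int]]:
    """(day offset, days_supply) pairs → (date, supply) fill series."""
    return [(day(d), s) for d, s in pairs]


def dispensing(
    pid: str = "P1",
    offset: int = 0,
    ingredient: str = "metformin",
    indication: Indication = Indication.DIABETES_ORAL,
    supply: int = 30,
) -> DispensingRecord:
    return DispensingRecord(
        patient_id=pid,
        fill_date=day(offset),
        ingredient=ingredient,
        indication=indication,
        days_supply=supply,
    )


def response(
    pid: str = "P1",
    source: Source = Source.ATSM,
    indication: Indication = Indication.DIABETES_ORAL,
    offset: int = 365,
    missed: int = 0,
) -> SelfReportResponse:
    return SelfReportResponse(
        patient_id=pid,
        source=source,
        indication=indication,
        response_date=day(offset),
        missed_days=missed,
    )


def eligible(pid: str = "P1", continuous: bool = True, dual: bool = False) -> PatientEligibility:
    return PatientEligibility(pid, continuous_benefits=continuous, dual_coverage=dual)


def random_fill_series(
    rng: np.random.Generator,
    n_fills_range: tuple[int, int] = (2, 8),
    supply_range: tuple[int, int] = (1, 120),
    spacing_range: tuple[int, int] = (1, 200),
) -> list[tuple[date, int]]:
    """Random strictly-increasing fill series for oracle comparisons."""
    n = int(rng.integers(n_fills_range[0], n_fills_range[1] + 1))
    offsets = np.cumsum(rng.integers(spacing_range[0], spacing_range[1] + 1, size=n))
    supplies = rng.integers(supply_range[0], supply_range[1] + 1, size=n)
    return [(day(int(o)), int(s)) for o, s in zip(offsets, supplies)]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
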