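"""Convergent-validity statistics: contingency tables, exact tests, concordance.

For each source × indication, respondents are cross-tabulated as missed-day
category (0 / 1 / 2–7) against claims-based adherence class (optimal CMG
<= 20% vs. suboptimal), and homogeneity of the optimal-adherence rate across
categories is tested with the Fisher–Freeman–Halton exact test — the r×c
generalization of Fisher's exact test that sums, under the fixed-margins
multivariate hypergeometric null, the probabilities of all tables no more
probable than the observed one.  Respondents without a calculable CMG are
excluded from the test but reported alongside, per category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from medgap.claims import Indication, SelfReportResponse, Source
from medgap.cmg import AdherenceClass, CmgResult
from medgap.selfreport import (
    CATEGORY_ORDER,
    ConcordancePair,
    MissedDayCategory,
    categorize_missed_days,
)


@dataclass
class ValidityTable:
    """3×2 cross-tabulation of missed-day category × CMG adherence class.

    ``counts[i][j]``: row i is the category (zero / one / two_to_seven),
    column 0 is optimal, column 1 suboptimal.  ``n_non_calculable[i]``
    counts respondents in category i whose CMG could not be computed; they
    sit outside the tested table.
    """

    indication: Indication
    source: Source
    counts: list[list[int]]
    n_non_calculable: list[int]
    p_value: float | None = None

    def __post_init__(self) -> None:
        if len(self.counts) != 3 or any(len(row) != 2 for row in self.counts):
            raise ValueError("counts must be a 3×2 matrix")
        if any(c < 0 for row in self.counts for c in row):
            raise ValueError("counts must be non-negative")
        if len(self.n_non_calculable) != 3:
            raise ValueError("n_non_calculable must have one entry per category")
        if self.p_value is not None and not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def n_tested(self) -> int:
        return sum(sum(row) for row in self.counts)


@dataclass
class ConcordanceSummary:
    """Agreement of missed-day reports between ATSM and interview.

    Pairs partition into concordant (equal reported days), higher disclosure
    on interview, and higher disclosure on ATSM; percentages are over the
    paired n and reported to one decimal, so they sum to 100 ± rounding.
    With zero pairs the percentages are undefined (``None``).
    """

    indication: Indication
    n_pairs: int
    pct_concordant: float | None
    pct_higher_interview: float | None
    pct_higher_atsm: float | None


def build_contingency(
    cmg_results: Iterable[CmgResult],
    selections: Iterable[SelfReportResponse],
    indication: Indication,
    source: Source,
) -> ValidityTable:
    """Tabulate respondents by missed-day category × adherence class.

    Each respondent with a selected response for this indication and source
    contributes one count: to the (category, optimal/suboptimal) cell if
    their CMG is calculable, otherwise to that category's non-calculable
    tally.  A respondent with no CMG record at all counts as non-calculable.
    """
    cmg_by_patient: dict[str, CmgResult] = {}
    for r in cmg_results:
        if r.indication is indication:
            cmg_by_patient[r.patient_id] = r

    counts = [[0, 0], [0, 0], [0, 0]]
    non_calc = [0, 0, 0]
    for resp in selections:
        if resp.indication is not indication or resp.source is not source:
            continue
        row = CATEGORY_ORDER.index(categorize_missed_days(resp.missed_days))
        result = cmg_by_patient.get(resp.patient_id)
        if result is None or not result.calculable:
            non_calc[row] += 1
        elif result.adherence_class is AdherenceClass.OPTIMAL:
            counts[row][0] += 1
        else:
            counts[row][1] += 1
    return ValidityTable(
        indication=indication, source=source, counts=counts, n_non_calculable=non_calc
    )


def _margin_tables(rows: Sequence[int], cols: Sequence[int]):
    """Yield all non-negative integer tables with the given margins."""
    if len(rows) == 1:
        yield (tuple(cols),)
        return
    head, rest = rows[0], rows[1:]

    def compositions(remaining: int, caps: Sequence[int]):
        if len(caps) == 1:
            if remaining <= caps[0]:
                yield (remaining,)
            return
        for v in range(min(remaining, caps[0]) + 1):
            for tail in compositions(remaining - v, caps[1:]):
                yield (v,) + tail

    for first_row in compositions(head, cols):
        reduced = [c - v for c, v in zip(cols, first_row)]
        for tail in _margin_tables(rest, reduced):
            yield (first_row,) + tail


def _cell_factorial_product(table) -> int:
    out = 1
    for row in table:
        for cell in row:
            out *= math.factorial(cell)
    return out


def fisher_exact_rxc(counts) -> float:
    """Two-sided Fisher–Freeman–Halton exact test for an r×c table.

    Conditions on both margins: under the null of homogeneity the table
    follows a multivariate hypergeometric law, P(T) = (Π rᵢ! Π cⱼ!) /
    (n! Π aᵢⱼ!).  The two-sided p is the total probability of all tables
    with the observed margins whose probability does not exceed that of the
    observed table.  Probability ordering is resolved in exact integer
    arithmetic (P(T) <= P(obs) iff Π aᵢⱼ! >= the observed product), so no
    floating-point tolerance enters the comparison.  Rows and columns
    summing to zero are dropped; a table reduced to a single row or column
    carries no information and returns p = 1.
    """
    table = [[int(c) for c in row] for row in counts]
    if any(c < 0 for row in table for c in row):
        raise ValueError("contingency counts must be non-negative")
    if sum(sum(row) for row in table) == 0:
        raise ValueError("contingency table must have at least one positive entry")

    rows = [sum(row) for row in table]
    cols = [sum(col) for col in zip(*table)]
    keep_rows = [i for i, r in enumerate(rows) if r > 0]
    keep_cols = [j for j, c in enumerate(cols) if c > 0]
    table = [[table[i][j] for j in keep_cols] for i in keep_rows]
    rows = [rows[i] for i in keep_rows]
    cols = [cols[j] for j in keep_cols]
    if len(rows) <= 1 or len(cols) <= 1:
        return 1.0

    observed_product = _cell_factorial_product(table)
    margin_constant = 1
    for r in rows:
        margin_constant *= math.factorial(r)
    for c in cols:
        margin_constant *= math.factorial(c)
    n_factorial = math.factorial(sum(rows))

    p = Fraction(0)
    for candidate in _margin_tables(rows, cols):
        product = _cell_factorial_product(candidate)
        if product >= observed_product:  # P(candidate) <= P(observed)
            p += Fraction(margin_constant, n_factorial * product)
    return float(min(p, Fraction(1)))


def attach_p_value(table: ValidityTable) -> ValidityTable:
    """Compute and attach the exact-test p for a validity table.

    An all-zero tested table (every respondent non-calculable) gets p = None.
    """
    if table.n_tested == 0:
        table.p_value = None
        return table
    table.p_value = fisher_exact_rxc(table.counts)
    return table


def concordance_summary(
    pairs: Iterable[ConcordancePair], indication: Indication
) -> ConcordanceSummary:
    """Classify matched ATSM/interview reports and summarize as percentages.

    Comparison is on the raw 0–7 missed-day counts (not the 3 categories):
    concordant iff equal, otherwise attributed to whichever mode disclosed
    more missed days.
    """
    relevant = [p for p in pairs if p.indication is indication]
    n = len(relevant)
    if n == 0:
        return ConcordanceSummary(indication, 0, None, None, None)
    concordant = sum(1 for p in relevant if p.atsm_missed == p.interview_missed)
    higher_interview = sum(1 for p in relevant if p.interview_missed > p.atsm_missed)
    higher_atsm = sum(1 for p in relevant if p.atsm_missed > p.interview_missed)
    return ConcordanceSummary(
        indication=indication,
        n_pairs=n,
        pct_concordant=round(100.0 * concordant / n, 1),
        pct_higher_interview=round(100.0 * higher_interview / n, 1),
        pct_higher_atsm=round(100.0 * higher_atsm / n, 1),
    )
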