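"""Synthetic dispensing-claims cohort with known ground-truth adherence.

Real health-plan claims are confidential, so pipeline validation runs on a
generated cohort whose true adherence is known by construction.  Each
patient carries a daily pill-taking propensity p drawn from a Beta
distribution; refills are driven by supply exhaustion plus a non-adherence
delay, with the delay geometric with mean days_supply·(1−p)/p so that the
expected uncovered fraction of the refill cycle is 1−p.  Because every
refill interval then has length days_supply + delay against exactly
days_supply of supply, the realized uncovered fraction between first and
last fill is recorded exactly in the truth table, and the claims-side gap
measure must recover it with zero error — a closed-form acceptance surface
for the whole pipeline.

Seven-day recall responses are drawn as Binomial(7, 1−p) per assessment
mode, optionally thinned by a per-day disclosure probability to emulate the
under-reporting bias of self-report.  Designated fractions of patients get
exactly one fill or dual coverage, producing the non-calculable cases the
analysis must account for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from medgap.claims import (
    ANALYZABLE_INDICATIONS,
    DispensingRecord,
    Indication,
    PatientEligibility,
    SelfReportResponse,
    Source,
    write_dispensings,
    write_eligibility,
    write_selfreports,
)

#: One representative ingredient per indication class.  A single drug per
#: class keeps the claims-side gap measure identical to the recorded truth.
INGREDIENT_BY_INDICATION = {
    Indication.DIABETES_ORAL: "metformin",
    Indication.BLOOD_PRESSURE: "lisinopril",
    Indication.CHOLESTEROL: "simvastatin",
}


@dataclass(frozen=True)
class BehaviorParams:
    """Generator parameters; the defaults define the simulated conditions.

    adherence_alpha/beta
        Beta shape parameters for the per-patient taking propensity p
        (default Beta(8, 2): mean 0.8, matching a mostly-adherent managed
        cohort with a left tail of poor adherence).
    days_supply
        Days of supply per fill (default 30, the standard retail fill).
    disclosure_prob
        Probability each truly-missed recall day is disclosed (1 = honest).
    frac_single_fill / frac_dual_coverage
        Fractions of patients forced to exactly one fill, or flagged with
        dual coverage — the deliberate non-calculable contamination.
    response_offset_days
        Maximum days between a patient's ATSM response and interview.
    fixed_propensity
        If set, pins every patient's p to this value (limit checks).
    """

    n_patients: int = 200
    adherence_alpha: float = 8.0
    adherence_beta: float = 2.0
    days_supply: int = 30
    window_days: int = 365
    disclosure_prob: float = 1.0
    frac_single_fill: float = 0.10
    frac_dual_coverage: float = 0.05
    indications: Sequence[Indication] = ANALYZABLE_INDICATIONS
    seed: int = 0
    anchor_date: date = date(2011, 6, 1)
    response_offset_days: int = 7
    fixed_propensity: float | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("disclosure_prob", "frac_single_fill", "frac_dual_coverage"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.days_supply < 1:
            raise ValueError("days_supply must be >= 1")
        if self.window_days < self.days_supply:
            raise ValueError(
                f"window_days ({self.window_days}) shorter than days_supply "
                f"({self.days_supply}): no refill interval can fit"
            )
        if self.fixed_propensity is not None and not 0.0 < self.fixed_propensity <= 1.0:
            raise ValueError("fixed_propensity must lie in (0, 1]")
        bad = [i for i in self.indications if i not in INGREDIENT_BY_INDICATION]
        if bad:
            raise ValueError(f"unsupported indication(s) for simulation: {bad}")


@dataclass
class SyntheticCohort:
    """Generated tables plus the ground-truth record, ready for the pipeline."""

    params: BehaviorParams
    dispensings: list[DispensingRecord]
    eligibility: dict[str, PatientEligibility]
    selfreports: list[SelfReportResponse]
    truth: pd.DataFrame = field(repr=False)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "claims": outdir / "claims.csv",
            "eligibility": outdir / "eligibility.csv",
            "selfreport": outdir / "selfreport.csv",
            "truth": outdir / "truth.csv",
        }
        write_dispensings(self.dispensings, paths["claims"])
        write_eligibility(self.eligibility.values(), paths["eligibility"])
        write_selfreports(self.selfreports, paths["selfreport"])
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def _draw_delay(rng: np.random.Generator, p: float, days_supply: int) -> int:
    """Refill delay beyond supply exhaustion, geometric on {0, 1, 2, ...}.

    Success probability q = p / (p + days_supply·(1−p)) gives mean delay
    days_supply·(1−p)/p, so E[delay / (days_supply + delay)] ≈ 1 − p.
    """
    if p >= 1.0:
        return 0
    q = p / (p + days_supply * (1.0 - p))
    return int(rng.geometric(q)) - 1


def generate_cohort(params: BehaviorParams) -> SyntheticCohort:
    """Generate claims, eligibility, self-report and truth tables.

    Fully deterministic given ``params.seed``: contamination flags draw from
    one dedicated stream and each patient's behavior from its own spawned
    stream, so raising a contamination fraction flags more patients without
    disturbing anyone else's trajectory.
    """
    root = np.random.SeedSequence(params.seed)
    contamination_seq, behavior_seq = root.spawn(2)
    contamination_rng = np.random.default_rng(contamination_seq)
    patient_seqs = behavior_seq.spawn(params.n_patients)

    # One uniform per patient per contamination channel, drawn up front so
    # the flags depend only on (seed, n_patients) and the fraction cutoffs.
    u_dual = contamination_rng.random(params.n_patients)
    u_single = contamination_rng.random(params.n_patients)

    dispensings: list[DispensingRecord] = []
    eligibility: dict[str, PatientEligibility] = {}
    selfreports: list[SelfReportResponse] = []
    truth_rows: list[dict] = []

    for i in range(params.n_patients):
        pid = f"P{i:04d}"
        rng = np.random.default_rng(patient_seqs[i])
        dual = bool(u_dual[i] < params.frac_dual_coverage)
        single_fill = bool(u_single[i] < params.frac_single_fill)
        eligibility[pid] = PatientEligibility(
            pid, continuous_benefits=True, dual_coverage=dual
        )

        atsm_date = params.anchor_date + timedelta(days=int(rng.integers(0, 28)))
        interview_date = atsm_date + timedelta(
            days=int(rng.integers(0, params.response_offset_days + 1))
        )
        window_start = atsm_date - timedelta(days=params.window_days)

        for indication in params.indications:
            if params.fixed_propensity is not None:
                p = params.fixed_propensity
            else:
                p = float(rng.beta(params.adherence_alpha, params.adherence_beta))
                p = min(max(p, 1e-6), 1.0)
            ingredient = INGREDIENT_BY_INDICATION[indication]

            # First fill sits past both possible window starts (ATSM- and
            # interview-anchored) so every fill lies inside either lookback.
            first_offset = params.response_offset_days + int(rng.integers(0, 15))
            fill_day = window_start + timedelta(days=first_offset)
            fill_dates = [fill_day]
            delays: list[int] = []
            while True:
                delay = _draw_delay(rng, p, params.days_supply)
                nxt = fill_dates[-1] + timedelta(days=params.days_supply + delay)
                if nxt > atsm_date:
                    break
                fill_dates.append(nxt)
                delays.append(delay)

            if single_fill:
                fill_dates = fill_dates[:1]
                delays = []

            for d in fill_dates:
                dispensings.append(
                    DispensingRecord(
                        patient_id=pid,
                        fill_date=d,
                        ingredient=ingredient,
                        indication=indication,
                        days_supply=params.days_supply,
                    )
                )

            if len(fill_dates) >= 2:
                observed = sum(params.days_supply + d for d in delays)
                gap = sum(delays)
                true_gap_fraction: float = gap / observed
            else:
                true_gap_fraction = math.nan
            truth_rows.append(
                {
                    "patient_id": pid,
                    "indication": indication.value,
                    "p_true": p,
                    "true_gap_fraction": true_gap_fraction,
                    "n_fills": len(fill_dates),
                    "atsm_date": atsm_date.isoformat(),
                    "interview_date": interview_date.isoformat(),
                }
            )

            for source, resp_date in (
                (Source.ATSM, atsm_date),
                (Source.INTERVIEW, interview_date),
            ):
                missed_true = int(rng.binomial(7, 1.0 - p))
                disclosed = int(rng.binomial(missed_true, params.disclosure_prob))
                selfreports.append(
                    SelfReportResponse(
                        patient_id=pid,
                        source=source,
                        indication=indication,
                        response_date=resp_date,
                        missed_days=disclosed,
                    )
                )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id",
            "indication",
            "p_true",
            "true_gap_fraction",
            "n_fills",
            "atsm_date",
            "interview_date",
        ],
    )
    return SyntheticCohort(
        params=params,
        dispensings=dispensings,
        eligibility=eligibility,
        selfreports=selfreports,
        truth=truth,
    )


def recovery_report(truth: pd.DataFrame, cmg_results) -> pd.DataFrame:
    """Bias/RMSE of the claims-side CMG against the generator's ground truth.

    Joins calculable CMG results to the truth table on patient × indication
    and summarizes, per indication, the error of CMG against the realized
    uncovered-day fraction (must be exactly zero: both measure the same
    realized gaps) and against 1 − p_true (shrinks with the number of
    refills by the law of large numbers).
    """
    rows = [
        {
            "patient_id": r.patient_id,
            "indication": r.indication.value,
            "cmg": float(r.cmg),
        }
        for r in cmg_results
        if r.calculable
    ]
    measured = pd.DataFrame(rows, columns=["patient_id", "indication", "cmg"])
    joined = measured.merge(truth, on=["patient_id", "indication"], how="inner")
    joined = joined.dropna(subset=["true_gap_fraction"])
    if joined.empty:
        raise ValueError("no overlap between CMG results and truth table")

    def summarize(group: pd.DataFrame) -> pd.Series:
        err_truth = group["cmg"] - group["true_gap_fraction"]
        err_prop = group["cmg"] - (1.0 - group["p_true"])
        return pd.Series(
            {
                "n": len(group),
                "mean_cmg": group["cmg"].mean(),
                "mean_true_gap_fraction": group["true_gap_fraction"].mean(),
                "mean_one_minus_p": (1.0 - group["p_true"]).mean(),
                "bias_vs_truth": err_truth.mean(),
                "rmse_vs_truth": float(np.sqrt(np.mean(err_truth**2))),
                "bias_vs_propensity": err_prop.mean(),
                "rmse_vs_propensity": float(np.sqrt(np.mean(err_prop**2))),
            }
        )

    report = (
        joined.groupby("indication", sort=True)
        .apply(summarize, include_groups=False)
        .reset_index()
    )
    report["n"] = report["n"].astype(int)
    return report


def perfect_adherence_params(n_patients: int = 20, seed: int = 0) -> BehaviorParams:
    """Limit-case parameters: p ≡ 1, honest disclosure, no contamination."""
    return BehaviorParams(
        n_patients=n_patients,
        fixed_propensity=1.0,
        disclosure_prob=1.0,
        frac_single_fill=0.0,
        frac_dual_coverage=0.0,
        seed=seed,
    )


def with_seed(params: BehaviorParams, seed: int) -> BehaviorParams:
    """Copy of ``params`` with a different seed."""
    return replace(params, seed=seed)
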