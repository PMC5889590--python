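"""End-to-end orchestration: inputs → CMG → categorization → validity → report.

A run consumes either real claims/eligibility/self-report CSVs or a
synthetic cohort, computes the claims-side gap measure anchored separately
at each assessment mode's response date (the 12-month lookback precedes the
ATSM query and the interview independently), builds the validity tables and
concordance summary, and writes a reproducible report bundle: per-stage
CSVs, a human-readable summary, and a JSON manifest with the configuration
echo and exhaustive patient accounting.  All randomness lives in the
synthetic generator; the analysis path is fully deterministic, so reruns at
a fixed seed reproduce the bundle byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import pandas as pd

from medgap import claims as cm
from medgap.claims import (
    ANALYZABLE_INDICATIONS,
    DispensingRecord,
    Indication,
    PatientEligibility,
    SelfReportResponse,
    Source,
)
from medgap.cmg import CmgResult, LookbackWindow, compute_cohort_cmg
from medgap.selfreport import (
    CATEGORY_ORDER,
    pair_for_concordance,
    select_all_responses,
)
from medgap.simulate import BehaviorParams, generate_cohort, recovery_report
from medgap.stats import attach_p_value, build_contingency, concordance_summary

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Run configuration; defaults mirror the analysis design.

    Exactly one input mode: the three CSV paths, or synthetic parameters.
    ``cmg_threshold`` is the optimal-adherence bound on the gap fraction
    (default 20%); ``selection_mode`` picks the first or last completed
    response per patient × indication × source; ``pairing_window_days``
    bounds the ATSM–interview date difference for concordance pairs.
    """

    outdir: str | Path = "medgap_output"
    claims_path: str | Path | None = None
    eligibility_path: str | Path | None = None
    selfreport_path: str | Path | None = None
    synthetic: BehaviorParams | None = None
    window_days: int = 365
    cmg_threshold: Fraction = Fraction(1, 5)
    selection_mode: str = "first"
    pairing_window_days: int = 30
    aggregation_mode: str = "pooled_days"
    strict_parse: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        self.cmg_threshold = Fraction(str(self.cmg_threshold))
        if not 0 < self.cmg_threshold < 1:
            raise ValueError("cmg_threshold must lie in (0, 1)")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        if self.pairing_window_days < 0:
            raise ValueError("pairing_window_days must be >= 0")
        if self.selection_mode not in ("first", "last"):
            raise ValueError("selection_mode must be 'first' or 'last'")
        if self.aggregation_mode not in ("pooled_days", "mean_per_ingredient"):
            raise ValueError(
                "aggregation_mode must be 'pooled_days' or 'mean_per_ingredient'"
            )
        paths = (self.claims_path, self.eligibility_path, self.selfreport_path)
        if self.synthetic is None:
            if any(p is None for p in paths):
                raise ValueError(
                    "provide claims_path, eligibility_path and selfreport_path, "
                    "or synthetic parameters"
                )
        elif any(p is not None for p in paths):
            raise ValueError("synthetic mode and input paths are mutually exclusive")

    def echo(self) -> dict:
        # outdir is deliberately not echoed: the bundle must be byte-identical
        # across reruns regardless of where it is written
        out = {
            "window_days": self.window_days,
            "cmg_threshold": str(self.cmg_threshold),
            "selection_mode": self.selection_mode,
            "pairing_window_days": self.pairing_window_days,
            "aggregation_mode": self.aggregation_mode,
            "strict_parse": self.strict_parse,
            "seed": self.seed,
        }
        if self.synthetic is not None:
            out["synthetic"] = {
                k: (v.isoformat() if hasattr(v, "isoformat") else
                    [i.value for i in v] if k == "indications" else v)
                for k, v in vars(self.synthetic).items()
            }
        else:
            out["claims_path"] = str(self.claims_path)
            out["eligibility_path"] = str(self.eligibility_path)
            out["selfreport_path"] = str(self.selfreport_path)
        return out


@dataclass
class PipelineResult:
    """In-memory view of the report bundle (everything is also on disk)."""

    config: PipelineConfig
    cmg_results: dict[Source, list[CmgResult]]
    validity: pd.DataFrame
    summary: pd.DataFrame
    concordance: pd.DataFrame
    manifest: dict
    recovery: pd.DataFrame | None = None
    outdir: Path = field(default_factory=lambda: Path("medgap_output"))


def _load_inputs(
    config: PipelineConfig, outdir: Path
) -> tuple[
    list[DispensingRecord],
    dict[str, PatientEligibility],
    list[SelfReportResponse],
    pd.DataFrame | None,
    dict,
]:
    if config.synthetic is not None:
        cohort = generate_cohort(config.synthetic)
        cohort.write(outdir / "inputs")
        tallies = {"parse_errors": 0}
        return (
            cohort.dispensings,
            cohort.eligibility,
            cohort.selfreports,
            cohort.truth,
            tallies,
        )
    dispensings, rep_d = cm.read_dispensings(config.claims_path, config.strict_parse)
    eligibility, rep_e = cm.read_eligibility(config.eligibility_path, config.strict_parse)
    selfreports, rep_s = cm.read_selfreports(config.selfreport_path, config.strict_parse)
    tallies = {
        "parse_errors": len(rep_d.errors) + len(rep_e.errors) + len(rep_s.errors),
        "parse_error_detail": {
            "claims": [str(e) for e in rep_d.errors],
            "eligibility": [str(e) for e in rep_e.errors],
            "selfreport": [str(e) for e in rep_s.errors],
        },
    }
    return dispensings, eligibility, selfreports, None, tallies


def _account_patients(
    eligibility: dict[str, PatientEligibility],
    dispensings: list[DispensingRecord],
    selfreports: list[SelfReportResponse],
    cmg_results: dict[Source, list[CmgResult]],
) -> dict[str, str]:
    """Assign every patient exactly one accounting category.

    Precedence: dual_coverage → no_continuous_benefits → no_selfreport →
    no_calculable_cmg → analyzed.  Exhaustive and exclusive over the union
    of patients appearing in any input table.
    """
    universe = (
        set(eligibility)
        | {r.patient_id for r in dispensings}
        | {r.patient_id for r in selfreports}
    )
    responded = {r.patient_id for r in selfreports}
    calculable = {
        r.patient_id
        for results in cmg_results.values()
        for r in results
        if r.calculable
    }
    accounting: dict[str, str] = {}
    for pid in sorted(universe):
        elig = eligibility.get(pid)
        if elig is not None and elig.dual_coverage:
            accounting[pid] = "excluded_dual_coverage"
        elif elig is not None and not elig.continuous_benefits:
            accounting[pid] = "excluded_no_continuous_benefits"
        elif pid not in responded:
            accounting[pid] = "excluded_no_selfreport"
        elif pid not in calculable:
            accounting[pid] = "excluded_no_calculable_cmg"
        else:
            accounting[pid] = "analyzed"
    return accounting


def _cmg_frame(results: list[CmgResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "indication": r.indication.value,
                "observed_days": r.observed_days,
                "gap_days": r.gap_days,
                "cmg": float(r.cmg) if r.cmg is not None else "",
                "calculable": r.calculable,
                "non_calculable_reason": r.non_calculable_reason.value,
                "adherence_class": r.adherence_class.value,
            }
            for r in results
        ],
        columns=[
            "patient_id",
            "indication",
            "observed_days",
            "gap_days",
            "cmg",
            "calculable",
            "non_calculable_reason",
            "adherence_class",
        ],
    )


def _trace_frame(traces: dict) -> pd.DataFrame:
    rows = []
    for (pid, indication), intervals in sorted(
        traces.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        for iv in intervals:
            rows.append(
                {
                    "patient_id": pid,
                    "indication": indication.value,
                    "start_date": iv.start_date.isoformat(),
                    "end_date": iv.end_date.isoformat(),
                    "length_days": iv.length_days,
                    "supply_available": iv.supply_available,
                    "gap_days": iv.gap_days,
                    "carryover_out": iv.carryover_out,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "indication",
            "start_date",
            "end_date",
            "length_days",
            "supply_available",
            "gap_days",
            "carryover_out",
        ],
    )


def _summary_frame(
    cmg_results: dict[Source, list[CmgResult]], indications: list[Indication]
) -> pd.DataFrame:
    """Mean CMG (SD) and % optimal by source × indication, respondents only."""
    rows = []
    for source in (Source.ATSM, Source.INTERVIEW):
        for indication in indications:
            calc = [
                float(r.cmg)
                for r in cmg_results[source]
                if r.indication is indication and r.calculable
            ]
            n_all = sum(1 for r in cmg_results[source] if r.indication is indication)
            optimal = [
                r
                for r in cmg_results[source]
                if r.indication is indication
                and r.calculable
                and r.adherence_class.value == "optimal"
            ]
            series = pd.Series(calc, dtype=float)
            rows.append(
                {
                    "source": source.value,
                    "indication": indication.value,
                    "n_respondents": n_all,
                    "n_calculable": len(calc),
                    "mean_cmg": round(series.mean(), 4) if calc else "",
                    "sd_cmg": round(series.std(ddof=1), 4) if len(calc) > 1 else "",
                    "pct_optimal": round(100.0 * len(optimal) / len(calc), 1)
                    if calc
                    else "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "source",
            "indication",
            "n_respondents",
            "n_calculable",
            "mean_cmg",
            "sd_cmg",
            "pct_optimal",
        ],
    )


def _render_summary_text(
    summary: pd.DataFrame, validity: pd.DataFrame, concordance: pd.DataFrame
) -> str:
    lines = ["medgap run summary", "=" * 60, ""]
    lines.append("Mean CMG and optimal adherence by source × indication")
    lines.append("-" * 60)
    for _, row in summary.iterrows():
        lines.append(
            f"  {row['source']:<10} {row['indication']:<15} "
            f"n={row['n_calculable']:<5} mean CMG={row['mean_cmg']} "
            f"(SD {row['sd_cmg']})  optimal={row['pct_optimal']}%"
        )
    lines.append("")
    lines.append("Adherence class by missed-day category (exact-test p)")
    lines.append("-" * 60)
    for (source, indication), grp in validity.groupby(
        ["source", "indication"], sort=True
    ):
        p = grp["p_value"].iloc[0]
        p_text = f"p={p:.3g}" if p == p and p != "" else "p=NA"
        lines.append(f"  {source} / {indication} ({p_text})")
        for _, row in grp.iterrows():
            lines.append(
                f"    {row['category']:<14} optimal={row['optimal']:<4} "
                f"suboptimal={row['suboptimal']:<4} "
                f"non_calculable={row['non_calculable']}"
            )
    lines.append("")
    lines.append("ATSM vs interview concordance (raw missed-day counts)")
    lines.append("-" * 60)
    for _, row in concordance.iterrows():
        lines.append(
            f"  {row['indication']:<15} n={row['n_pairs']:<4} "
            f"concordant={row['pct_concordant']}%  "
            f"higher on interview={row['pct_higher_interview']}%  "
            f"higher on ATSM={row['pct_higher_atsm']}%"
        )
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write the report bundle to config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        dispensings, eligibility, selfreports, truth, tallies = _load_inputs(
            config, outdir
        )
    except Exception as exc:  # noqa: BLE001 - rewrap with stage name
        raise PipelineError(f"input stage failed: {exc}") from exc

    try:
        kept, removal_tally = cm.filter_cohort(dispensings, eligibility)
    except Exception as exc:
        raise PipelineError(f"cohort-filter stage failed: {exc}") from exc

    indications = [
        i for i in ANALYZABLE_INDICATIONS
        if any(r.indication is i for r in selfreports)
        or any(r.indication is i for r in dispensings)
    ] or list(ANALYZABLE_INDICATIONS)

    selections = select_all_responses(selfreports, config.selection_mode)
    by_source: dict[Source, list[SelfReportResponse]] = {
        Source.ATSM: [],
        Source.INTERVIEW: [],
    }
    for (pid, source, indication), resp in selections.items():
        by_source[source].append(resp)

    cmg_results: dict[Source, list[CmgResult]] = {}
    traces: dict[Source, dict] = {}
    try:
        for source in (Source.ATSM, Source.INTERVIEW):
            windows = {
                (r.patient_id, r.indication): LookbackWindow(
                    r.response_date, config.window_days
                )
                for r in by_source[source]
            }
            cmg_results[source], traces[source] = compute_cohort_cmg(
                kept,
                eligibility,
                windows,
                threshold=config.cmg_threshold,
                aggregation=config.aggregation_mode,
            )
    except Exception as exc:
        raise PipelineError(f"cmg stage failed: {exc}") from exc

    try:
        validity_rows = []
        for source in (Source.ATSM, Source.INTERVIEW):
            for indication in indications:
                table = build_contingency(
                    cmg_results[source], by_source[source], indication, source
                )
                attach_p_value(table)
                for row_idx, category in enumerate(CATEGORY_ORDER):
                    validity_rows.append(
                        {
                            "source": source.value,
                            "indication": indication.value,
                            "category": category.value,
                            "optimal": table.counts[row_idx][0],
                            "suboptimal": table.counts[row_idx][1],
                            "non_calculable": table.n_non_calculable[row_idx],
                            "p_value": table.p_value
                            if table.p_value is not None
                            else float("nan"),
                        }
                    )
        validity = pd.DataFrame(
            validity_rows,
            columns=[
                "source",
                "indication",
                "category",
                "optimal",
                "suboptimal",
                "non_calculable",
                "p_value",
            ],
        )

        pairs, pair_tally = pair_for_concordance(
            by_source[Source.ATSM],
            by_source[Source.INTERVIEW],
            config.pairing_window_days,
        )
        concordance_rows = []
        for indication in indications:
            s = concordance_summary(pairs, indication)
            concordance_rows.append(
                {
                    "indication": indication.value,
                    "n_pairs": s.n_pairs,
                    "pct_concordant": s.pct_concordant,
                    "pct_higher_interview": s.pct_higher_interview,
                    "pct_higher_atsm": s.pct_higher_atsm,
                }
            )
        concordance = pd.DataFrame(
            concordance_rows,
            columns=[
                "indication",
                "n_pairs",
                "pct_concordant",
                "pct_higher_interview",
                "pct_higher_atsm",
            ],
        )
    except Exception as exc:
        raise PipelineError(f"validity stage failed: {exc}") from exc

    summary = _summary_frame(cmg_results, indications)

    recovery = None
    if truth is not None:
        # ATSM-anchored results suffice for recovery; both anchors see the
        # same fills by construction, so either join gives zero error.
        recovery = recovery_report(truth, cmg_results[Source.ATSM])

    accounting = _account_patients(eligibility, dispensings, selfreports, cmg_results)
    accounting_tally: dict[str, int] = {}
    for category in accounting.values():
        accounting_tally[category] = accounting_tally.get(category, 0) + 1

    manifest = {
        "config": config.echo(),
        "n_input_dispensings": len(dispensings),
        "n_input_patients": len(
            set(eligibility)
            | {r.patient_id for r in dispensings}
            | {r.patient_id for r in selfreports}
        ),
        "n_selfreports": len(selfreports),
        "n_selected_responses": {
            s.value: len(by_source[s]) for s in (Source.ATSM, Source.INTERVIEW)
        },
        "removed_fills": removal_tally,
        "pairing": pair_tally | {"paired": len(pairs)},
        "patient_accounting": accounting_tally,
        "patient_accounting_detail": accounting,
        "non_calculable_reasons": {
            source.value: {
                reason: sum(
                    1
                    for r in cmg_results[source]
                    if r.non_calculable_reason.value == reason
                )
                for reason in sorted(
                    {r.non_calculable_reason.value for r in cmg_results[source]}
                )
            }
            for source in (Source.ATSM, Source.INTERVIEW)
        },
        **tallies,
    }

    # --- write the bundle ---------------------------------------------------
    pairs_frame = pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "indication": p.indication.value,
                "atsm_missed": p.atsm_missed,
                "interview_missed": p.interview_missed,
                "atsm_date": p.atsm_date.isoformat(),
                "interview_date": p.interview_date.isoformat(),
            }
            for p in pairs
        ],
        columns=[
            "patient_id",
            "indication",
            "atsm_missed",
            "interview_missed",
            "atsm_date",
            "interview_date",
        ],
    )
    selections_frame = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "source": r.source.value,
                "indication": r.indication.value,
                "response_date": r.response_date.isoformat(),
                "missed_days": r.missed_days,
            }
            for key in sorted(
                selections, key=lambda k: (k[0], k[1].value, k[2].value)
            )
            for r in [selections[key]]
        ],
        columns=["patient_id", "source", "indication", "response_date", "missed_days"],
    )

    for source in (Source.ATSM, Source.INTERVIEW):
        _cmg_frame(cmg_results[source]).to_csv(
            outdir / f"cmg_{source.value}.csv", index=False
        )
        _trace_frame(traces[source]).to_csv(
            outdir / f"intervals_{source.value}.csv", index=False
        )
    selections_frame.to_csv(outdir / "selections.csv", index=False)
    pairs_frame.to_csv(outdir / "pairs.csv", index=False)
    validity.to_csv(outdir / "validity_tables.csv", index=False)
    concordance.to_csv(outdir / "concordance.csv", index=False)
    summary.to_csv(outdir / "summary.csv", index=False)
    if recovery is not None:
        recovery.to_csv(outdir / "recovery.csv", index=False)
    (outdir / "summary.txt").write_text(
        _render_summary_text(summary, validity, concordance)
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        config=config,
        cmg_results=cmg_results,
        validity=validity,
        summary=summary,
        concordance=concordance,
        manifest=manifest,
        recovery=recovery,
        outdir=outdir,
    )
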