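"""End-to-end orchestration: simulate (or load) -> metrics -> report.

This module is the library's "run the whole study" surface.  Each stage is
an ordinary function so scripts can compose them:

- :func:`analyze_cohort` turns a cohort into the per-maneuver metrics
  table, per-patient summaries and a findings list;
- :func:`build_report` computes the group-comparison table, the cut-off
  rule's diagnostic accuracy, the threshold sweep and the constipation
  chi-square, bundling every number into one JSON-serialisable dict;
- :func:`run_pipeline` drives simulation/IO/analysis/report from a
  :class:`PipelineConfig` and writes all artifacts (CSV tables, JSON
  summary, optional figures) under the output directory.

Everything is deterministic given the config's seed: re-running a config
writes byte-identical JSON summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import plots
from .classify import CutoffRule, DiagnosticAccuracy, evaluate_rule, threshold_sweep
from .io import (
    Cohort,
    Finding,
    findings_frame,
    read_cohort,
    write_cohort,
)
from .metrics import (
    ManeuverMetrics,
    MetricsError,
    PatientSummary,
    aggregate_patient,
    maneuver_metrics,
)
from .simulate import SimulationConfig, simulate_cohort
from .stats import GroupComparisonReport, build_group_report, constipation_comparison

logger = logging.getLogger("anometry")

DEFAULT_ANTERIOR_GRID = tuple(float(v) for v in range(50, 130, 5))  # includes 75
DEFAULT_RATIO_GRID = tuple(round(0.1 * k, 1) for k in range(4, 11))  # includes 0.7


@dataclass
class PipelineConfig:
    """Nested configuration for the full pipeline."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    rule: CutoffRule = field(default_factory=CutoffRule)
    smoothing_window: int = 3
    max_maneuvers: int = 6
    unit_of_analysis: str = "patient"
    confidence: float = 0.95
    output_dir: str = "anometry_out"
    make_figures: bool = False

    def __post_init__(self) -> None:
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        if self.max_maneuvers < 1:
            raise ValueError("max_maneuvers must be >= 1")
        if self.unit_of_analysis not in ("patient", "maneuver"):
            raise ValueError("unit_of_analysis must be 'patient' or 'maneuver'")
        if not 0.5 < self.confidence < 1.0:
            raise ValueError("confidence must be in (0.5, 1)")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulation", {})
        rule = data.pop("rule", {})
        _reject_unknown(sim, SimulationConfig, "simulation")
        _reject_unknown(rule, CutoffRule, "rule")
        _reject_unknown(data, cls, "pipeline")
        return cls(
            simulation=SimulationConfig(**sim),
            rule=CutoffRule(**rule),
            **data,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _reject_unknown(data: dict, cls: type, section: str) -> None:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {section} config keys: {sorted(unknown)}")
    for name in ("simulation", "rule"):
        known.discard(name)


@dataclass
class AnalysisResult:
    maneuver_table: pd.DataFrame
    summaries: list[PatientSummary]
    findings: list[Finding]


def maneuver_frame(metrics: Iterable[ManeuverMetrics], groups: dict[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for m in metrics:
        rows.append(
            {
                "patient_id": m.patient_id,
                "maneuver_id": m.maneuver_id,
                "group": (groups or {}).get(m.patient_id, "unknown"),
                "hpz_index": m.hpz_index,
                "hpz_axial_cm": m.hpz_axial,
                "mean_circumferential": m.mean_circumferential,
                "mean_anterior": m.mean_anterior,
                "ratio": m.ratio,
            }
        )
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: Iterable[PatientSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row: dict[str, Any] = {
            "patient_id": s.patient_id,
            "group": s.group_label,
            "constipated": s.constipated,
            "n_maneuvers_used": s.n_maneuvers_used,
            "n_maneuvers_dropped": s.n_maneuvers_dropped,
        }
        for metric in ("circumferential", "anterior", "ratio"):
            for agg in ("min", "mean", "max"):
                row[f"{metric}_{agg}"] = s.get(metric, agg)
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_cohort(
    cohort: Cohort,
    smoothing_window: int = 3,
    max_maneuvers: int = 6,
) -> AnalysisResult:
    """Per-maneuver metrics and per-patient summaries for a whole cohort.

    Corrupt or degenerate maneuvers/patients are dropped with findings,
    never a crash: analysis of the rest continues.
    """
    findings: list[Finding] = []
    all_metrics: list[ManeuverMetrics] = []
    summaries: list[PatientSummary] = []
    groups = {p.patient_id: p.group_label for p in cohort.patients}
    for patient in cohort.patients:
        patient_metrics: list[ManeuverMetrics] = []
        for rec in sorted(patient.recordings, key=lambda r: r.maneuver_id):
            try:
                patient_metrics.append(maneuver_metrics(rec, smoothing_window))
            except MetricsError as exc:
                findings.append(
                    Finding("error", "maneuver-failed", str(exc), patient.patient_id, rec.maneuver_id)
                )
        all_metrics.extend(patient_metrics)
        try:
            summaries.append(
                aggregate_patient(
                    patient_metrics,
                    patient.patient_id,
                    group_label=patient.group_label,
                    constipated=patient.constipated,
                    max_maneuvers=max_maneuvers,
                    findings=findings,
                )
            )
        except MetricsError as exc:
            findings.append(Finding("error", "patient-failed", str(exc), patient.patient_id))
    for f in findings:
        logger.warning("%s [%s] %s", f.level, f.code, f.message)
    return AnalysisResult(
        maneuver_table=maneuver_frame(all_metrics, groups),
        summaries=summaries,
        findings=findings,
    )


def _accuracy_dict(acc: DiagnosticAccuracy) -> dict[str, Any]:
    return {
        "true_positives": acc.true_positives,
        "false_negatives": acc.false_negatives,
        "true_negatives": acc.true_negatives,
        "false_positives": acc.false_positives,
        "sensitivity": acc.sensitivity,
        "specificity": acc.specificity,
        "sensitivity_ci": list(acc.sensitivity_ci) if acc.sensitivity_ci else None,
        "specificity_ci": list(acc.specificity_ci) if acc.specificity_ci else None,
        "confidence": acc.confidence,
        "notices": [f.message for f in acc.findings],
    }


def build_report(
    analysis: AnalysisResult,
    cohort: Cohort,
    rule: CutoffRule = CutoffRule(),
    unit_of_analysis: str = "patient",
    confidence: float = 0.95,
    anterior_grid: Sequence[float] = DEFAULT_ANTERIOR_GRID,
    ratio_grid: Sequence[float] = DEFAULT_RATIO_GRID,
) -> dict[str, Any]:
    """Compute every cohort-level statistic and bundle it into one dict.

    Sections: ``group_comparison`` (the 9-row table), ``accuracy`` (the
    configured rule; omitted with a notice when no truth labels exist),
    ``threshold_sweep`` and ``constipation``.  All numbers in any rendered
    artifact come from this dict.
    """
    report: dict[str, Any] = {
        "n_patients": len(cohort.patients),
        "n_group_a": sum(p.group_label == "A" for p in cohort.patients),
        "n_group_b": sum(p.group_label == "B" for p in cohort.patients),
        "unit_of_analysis": unit_of_analysis,
        "rule": {
            "anterior_threshold": rule.anterior_threshold,
            "ratio_threshold": rule.ratio_threshold,
            "combination": rule.combination,
            "aggregate": rule.aggregate,
        },
    }
    has_truth = report["n_group_a"] > 0 and report["n_group_b"] > 0

    if has_truth:
        group_report = build_group_report(
            analysis.summaries,
            unit_of_analysis=unit_of_analysis,
            maneuver_table=analysis.maneuver_table,
        )
        report["group_comparison"] = group_report.table.to_dict(orient="records")
        acc = evaluate_rule(analysis.summaries, rule, confidence)
        report["accuracy"] = _accuracy_dict(acc)
        sweep = threshold_sweep(
            analysis.summaries,
            anterior_grid,
            ratio_grid,
            combination=rule.combination,
            aggregate=rule.aggregate,
            confidence=confidence,
        )
        best = sweep.loc[sweep["youden"].idxmax()]
        report["threshold_sweep"] = {
            "n_grid_points": int(len(sweep)),
            "best_youden": {
                "anterior_threshold": float(best["anterior_threshold"]),
                "ratio_threshold": float(best["ratio_threshold"]),
                "sensitivity": float(best["sensitivity"]),
                "specificity": float(best["specificity"]),
                "youden": float(best["youden"]),
            },
        }
        report["_sweep_table"] = sweep  # popped before JSON serialisation
    else:
        report["accuracy"] = None
        report["notices"] = ["no ground-truth group labels; accuracy section omitted"]

    constipation = constipation_comparison(cohort.patients)
    report["constipation"] = {
        "statistic": constipation.statistic_value,
        "p_value": constipation.p_value,
        "df": constipation.df,
        "table": constipation.extra.get("table"),
        "rate_a": constipation.extra.get("rate_a"),
        "rate_b": constipation.extra.get("rate_b"),
        "excluded": constipation.extra.get("excluded"),
        "notices": [f.message for f in constipation.findings],
    }
    return report


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def run_pipeline(
    config: PipelineConfig,
    cohort_path: str | Path | None = None,
) -> dict[str, Any]:
    """Simulate (or read ``cohort_path``), analyze and report.

    Writes under ``config.output_dir``: the cohort interchange files (when
    simulating), ``maneuver_metrics.csv``, ``patient_metrics.csv``,
    ``group_report.csv``, ``threshold_sweep.csv``, ``findings.csv``,
    ``summary.json`` and (optionally) the boxplot/scatter figures.
    Returns the report dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cohort_path is None:
        cohort = simulate_cohort(config.simulation)
        write_cohort(cohort, out / "cohort")
        logger.info(
            "simulated cohort: %d patients (%d group A, %d group B)",
            len(cohort.patients),
            sum(p.group_label == "A" for p in cohort.patients),
            sum(p.group_label == "B" for p in cohort.patients),
        )
    else:
        cohort = read_cohort(cohort_path)

    analysis = analyze_cohort(cohort, config.smoothing_window, config.max_maneuvers)
    analysis.maneuver_table.to_csv(out / "maneuver_metrics.csv", index=False)
    patient_frame = summaries_to_frame(analysis.summaries)
    patient_frame.to_csv(out / "patient_metrics.csv", index=False)
    findings_frame(analysis.findings).to_csv(out / "findings.csv", index=False)

    report = build_report(
        analysis,
        cohort,
        rule=config.rule,
        unit_of_analysis=config.unit_of_analysis,
        confidence=config.confidence,
    )
    sweep = report.pop("_sweep_table", None)
    if sweep is not None:
        sweep.to_csv(out / "threshold_sweep.csv", index=False)
    if "group_comparison" in report:
        pd.DataFrame(report["group_comparison"]).to_csv(out / "group_report.csv", index=False)

    (out / "summary.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=_json_default)
    )

    if config.make_figures and not patient_frame.empty:
        plots.metric_boxplots(patient_frame, out / "metric_boxplots.png")
        plots.cutoff_scatter(patient_frame, config.rule, out / "cutoff_scatter.png")

    return report
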