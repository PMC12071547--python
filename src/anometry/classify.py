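"""Cut-off classification of an anus outside the sphincter complex.

The decision rule flags a patient as *abnormal* when the chosen
per-patient aggregate (default: the mean across maneuvers) of the anterior
pressure falls strictly below 75 mmHg AND the anterior-to-circumferential
ratio falls strictly below 0.7.  Diagnostic accuracy against a reference
standard (group A = condition positive) is reported as a confusion matrix
with sensitivity and specificity and exact two-sided Clopper-Pearson
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta

from .io import Finding
from .metrics import PatientSummary

ABNORMAL = "abnormal"
NORMAL = "normal"


@dataclass(frozen=True)
class CutoffRule:
    anterior_threshold: float = 75.0  # mmHg
    ratio_threshold: float = 0.7
    combination: str = "AND"  # "AND" | "OR"
    aggregate: str = "mean"  # which PatientSummary statistic feeds the rule

    def __post_init__(self) -> None:
        # 0 and +inf are allowed so threshold sweeps can include the
        # flag-nobody / flag-everybody corners.
        if self.anterior_threshold < 0 or self.ratio_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if self.combination not in ("AND", "OR"):
            raise ValueError(f"combination must be AND or OR, got {self.combination!r}")
        if self.aggregate not in ("min", "mean", "max"):
            raise ValueError(f"aggregate must be min/mean/max, got {self.aggregate!r}")


@dataclass(frozen=True)
class DiagnosticAccuracy:
    true_positives: int
    false_negatives: int
    true_negatives: int
    false_positives: int
    sensitivity: float | None
    specificity: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity_ci: tuple[float, float] | None
    confidence: float = 0.95
    findings: tuple[Finding, ...] = ()


def clopper_pearson(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial CI by inverting the binomial tail tests.

    Uses the beta-quantile form: lower = B(alpha/2; k, n-k+1),
    upper = B(1-alpha/2; k+1, n-k), with the conventional closed ends at
    k = 0 (lower 0) and k = n (upper 1).
    """
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    alpha = 1.0 - confidence
    lower = 0.0 if k == 0 else float(beta.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lower, upper


def classify_patient(summary: PatientSummary, rule: CutoffRule = CutoffRule()) -> str:
    """Apply the cut-off rule; strict '<' comparisons, deterministic."""
    anterior = summary.get("anterior", rule.aggregate)
    ratio = summary.get("ratio", rule.aggregate)
    low_anterior = anterior < rule.anterior_threshold
    low_ratio = ratio < rule.ratio_threshold
    flagged = (low_anterior and low_ratio) if rule.combination == "AND" else (
        low_anterior or low_ratio
    )
    return ABNORMAL if flagged else NORMAL


def evaluate_rule(
    summaries: Iterable[PatientSummary],
    rule: CutoffRule = CutoffRule(),
    confidence: float = 0.95,
) -> DiagnosticAccuracy:
    """Confusion matrix of the rule against the group labels.

    Group A is condition positive (abnormal sphincter on the reference
    standard).  Patients with an unknown group label are skipped.  An empty
    truth class leaves the corresponding metric None with a finding.
    """
    tp = fn = tn = fp = 0
    findings: list[Finding] = []
    n_unknown = 0
    for s in summaries:
        if s.group_label not in ("A", "B"):
            n_unknown += 1
            continue
        predicted_abnormal = classify_patient(s, rule) == ABNORMAL
        if s.group_label == "A":
            tp += predicted_abnormal
            fn += not predicted_abnormal
        else:
            fp += predicted_abnormal
            tn += not predicted_abnormal
    if n_unknown:
        findings.append(
            Finding("warning", "unknown-truth", f"{n_unknown} patient(s) without group label skipped")
        )

    if tp + fn > 0:
        sensitivity = tp / (tp + fn)
        sens_ci = clopper_pearson(tp, tp + fn, confidence)
    else:
        sensitivity, sens_ci = None, None
        findings.append(Finding("warning", "no-positives", "no condition-positive patients; sensitivity undefined"))
    if tn + fp > 0:
        specificity = tn / (tn + fp)
        spec_ci = clopper_pearson(tn, tn + fp, confidence)
    else:
        specificity, spec_ci = None, None
        findings.append(Finding("warning", "no-negatives", "no condition-negative patients; specificity undefined"))

    return DiagnosticAccuracy(
        true_positives=tp,
        false_negatives=fn,
        true_negatives=tn,
        false_positives=fp,
        sensitivity=sensitivity,
        specificity=specificity,
        sensitivity_ci=sens_ci,
        specificity_ci=spec_ci,
        confidence=confidence,
        findings=tuple(findings),
    )


def threshold_sweep(
    summaries: Sequence[PatientSummary],
    anterior_grid: Sequence[float],
    ratio_grid: Sequence[float],
    combination: str = "AND",
    aggregate: str = "mean",
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Diagnostic accuracy over a grid of (anterior, ratio) thresholds.

    Returns one row per grid point with the confusion counts, sensitivity,
    specificity, their CIs and the Youden index (sens + spec - 1); a
    systematic version of reading the cut-off off the scatter plot.
    """
    if len(anterior_grid) == 0 or len(ratio_grid) == 0:
        raise ValueError("threshold grids must be non-empty")
    summaries = list(summaries)
    rows = []
    for a_thr in anterior_grid:
        for r_thr in ratio_grid:
            rule = CutoffRule(
                anterior_threshold=float(a_thr),
                ratio_threshold=float(r_thr),
                combination=combination,
                aggregate=aggregate,
            )
            acc = evaluate_rule(summaries, rule, confidence)
            youden = (
                acc.sensitivity + acc.specificity - 1.0
                if acc.sensitivity is not None and acc.specificity is not None
                else np.nan
            )
            rows.append(
                {
                    "anterior_threshold": float(a_thr),
                    "ratio_threshold": float(r_thr),
                    "tp": acc.true_positives,
                    "fn": acc.false_negatives,
                    "tn": acc.true_negatives,
                    "fp": acc.false_positives,
                    "sensitivity": acc.sensitivity,
                    "specificity": acc.specificity,
                    "sensitivity_ci_low": acc.sensitivity_ci[0] if acc.sensitivity_ci else np.nan,
                    "sensitivity_ci_high": acc.sensitivity_ci[1] if acc.sensitivity_ci else np.nan,
                    "specificity_ci_low": acc.specificity_ci[0] if acc.specificity_ci else np.nan,
                    "specificity_ci_high": acc.specificity_ci[1] if acc.specificity_ci else np.nan,
                    "youden": youden,
                }
            )
    return pd.DataFrame(rows)
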