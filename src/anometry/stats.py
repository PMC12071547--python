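"""Group-comparison statistics, written from first principles.

Implements the two tests the cohort analysis needs — the Mann-Whitney U
test (midranks for ties, tie-corrected normal approximation, optional
exact p by complete enumeration) and the Pearson chi-square test for a
2x2 table (optional Yates correction) — plus the Table-1-style report:
group means of each per-patient aggregate with U and p per row.

scipy supplies only numerical primitives (rank assignment and the normal /
chi-square tail functions); the test logic itself lives here so it can be
cross-checked against independent oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, rankdata

from .io import Finding, PatientRecord
from .metrics import AGGREGATES, METRICS, PatientSummary

EXACT_ENUMERATION_LIMIT = 400  # exact p offered while n1*n2 <= this


@dataclass(frozen=True)
class TestResult:
    statistic_name: str
    statistic_value: float | None
    p_value: float | None
    z_value: float | None = None
    df: int | None = None
    n1: int | None = None
    n2: int | None = None
    unit_of_analysis: str | None = None
    method: str | None = None
    extra: dict = field(default_factory=dict)
    findings: tuple[Finding, ...] = ()


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _exact_u_pvalue(pooled: np.ndarray, n1: int, u_min: float) -> float:
    """Two-sided exact p for the Mann-Whitney U by complete enumeration.

    Dynamic programme over tie groups in increasing value order: choosing
    ``j`` sample-1 members from a tie group of size ``t`` adds
    ``j * (#sample-2 already placed) + j*(t-j)/2`` to U1.  Weights are
    binomial, so the distribution enumerated is exactly the permutation
    distribution over all C(n, n1) group assignments.  U is tracked as
    2*U1 to stay integral with ties.
    """
    values, counts = np.unique(pooled, return_counts=True)
    n = len(pooled)
    n2 = n - n1
    # dp maps (a_used, 2*U1) -> number of assignments
    dp: dict[tuple[int, int], int] = {(0, 0): 1}
    processed = 0
    for t in counts:
        t = int(t)
        new_dp: dict[tuple[int, int], int] = {}
        for (a_used, two_u), ways in dp.items():
            b_before = processed - a_used
            for j in range(0, min(t, n1 - a_used) + 1):
                key = (a_used + j, two_u + 2 * j * b_before + j * (t - j))
                new_dp[key] = new_dp.get(key, 0) + ways * math.comb(t, j)
        dp = new_dp
        processed += t
    dist: dict[int, int] = {}
    for (a_used, two_u), ways in dp.items():
        if a_used == n1:
            dist[two_u] = dist.get(two_u, 0) + ways
    total = math.comb(n, n1)
    two_u_obs = int(round(2 * u_min))
    two_u_max = 2 * n1 * n2
    count = sum(w for u, w in dist.items() if u <= two_u_obs)
    count += sum(w for u, w in dist.items() if u >= two_u_max - two_u_obs)
    return min(1.0, count / total)


def mann_whitney_u(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    method: str = "auto",
    unit_of_analysis: str | None = None,
) -> TestResult:
    """Mann-Whitney U test with midranks for ties.

    U1 = R1 - n1(n1+1)/2 (equivalently the count of (a, b) pairs with
    a > b plus half the ties); the reported statistic is min(U1, U2), the
    online-calculator convention.  ``method`` is "normal" (tie-corrected
    normal approximation, no continuity correction), "exact" (complete
    enumeration of the permutation distribution) or "auto" (exact while
    n1*n2 <= 400, else normal).  A fully tied pooled sample has zero
    variance; p is then 1 by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if method not in ("auto", "normal", "exact"):
        raise ValueError(f"unknown method {method!r}")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u_min = min(u1, u2)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    if sigma2 > 0:
        z = (u1 - mu) / math.sqrt(sigma2)
        p_normal = float(2.0 * norm.sf(abs(z)))
    else:
        z = None
        p_normal = 1.0

    use_exact = method == "exact" or (method == "auto" and n1 * n2 <= EXACT_ENUMERATION_LIMIT)
    if use_exact:
        p = _exact_u_pvalue(pooled, n1, u_min)
        method_used = "exact"
    else:
        p = p_normal
        method_used = "normal"

    return TestResult(
        statistic_name="mann-whitney-u",
        statistic_value=u_min,
        p_value=p,
        z_value=z,
        n1=n1,
        n2=n2,
        unit_of_analysis=unit_of_analysis,
        method=method_used,
        extra={"u1": u1, "u2": u2, "p_normal": p_normal},
    )


def chi_square_2x2(
    table: Sequence[Sequence[float]] | np.ndarray,
    yates: bool = False,
) -> TestResult:
    """Pearson chi-square for a 2x2 table of counts, df = 1.

    X^2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); with ``yates`` the
    |ad - bc| term is reduced by N/2 (clamped at zero).  A zero marginal
    leaves the statistic undefined (None) with an error-level finding
    instead of raising; expected cells below 5 raise a small-count
    warning finding.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    n = float(t.sum())
    if n <= 0:
        raise ValueError("table total must be positive")
    (a, b), (c, d) = t
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    findings: list[Finding] = []
    if min(row1, row2, col1, col2) == 0:
        findings.append(
            Finding("error", "zero-marginal", "a zero marginal leaves the chi-square undefined")
        )
        return TestResult(
            statistic_name="chi-square",
            statistic_value=None,
            p_value=None,
            df=1,
            n1=int(row1),
            n2=int(row2),
            method="yates" if yates else "pearson",
            extra={"table": t.tolist()},
            findings=tuple(findings),
        )
    expected = np.outer([row1, row2], [col1, col2]) / n
    if (expected < 5).any():
        findings.append(
            Finding("warning", "small-counts", "expected cell count below 5; chi-square approximation is weak")
        )
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    statistic = n * diff**2 / (row1 * row2 * col1 * col2)
    p = float(chi2_dist.sf(statistic, df=1))
    return TestResult(
        statistic_name="chi-square",
        statistic_value=float(statistic),
        p_value=p,
        df=1,
        n1=int(row1),
        n2=int(row2),
        method="yates" if yates else "pearson",
        extra={"table": t.tolist(), "expected": expected.tolist()},
        findings=tuple(findings),
    )


@dataclass(frozen=True)
class GroupComparisonReport:
    """The Table-1-shaped report: one row per metric x aggregate."""

    table: pd.DataFrame
    unit_of_analysis: str

    def to_markdown(self) -> str:
        cols = ["metric", "aggregate", "group_a_mean", "group_b_mean", "u_statistic", "p_value"]
        t = self.table[cols].copy()
        for c in ("group_a_mean", "group_b_mean", "u_statistic"):
            t[c] = t[c].map(lambda v: f"{v:.1f}" if abs(v) >= 10 else f"{v:.2f}")
        t["p_value"] = t["p_value"].map(lambda v: f"{v:.3f}")
        return t.to_markdown(index=False)


def build_group_report(
    summaries: Iterable[PatientSummary],
    unit_of_analysis: str = "patient",
    maneuver_table: pd.DataFrame | None = None,
    method: str = "auto",
    holm: bool = False,
) -> GroupComparisonReport:
    """Group A vs B comparison of each metric.

    With the default patient unit: 9 rows (3 metrics x min/mean/max of the
    per-patient aggregates), group means being arithmetic means over
    patients.  With ``unit_of_analysis='maneuver'`` a per-maneuver table
    (columns ``group``, ``mean_circumferential``, ``mean_anterior``,
    ``ratio``) is compared instead, 3 rows.  Raw p-values by default; the
    Holm step-down adjustment is available but off, matching how such
    tables are conventionally reported.
    """
    rows = []
    if unit_of_analysis == "patient":
        summaries = [s for s in summaries if s.group_label in ("A", "B")]
        group_a = [s for s in summaries if s.group_label == "A"]
        group_b = [s for s in summaries if s.group_label == "B"]
        if not group_a or not group_b:
            raise ValueError("need at least one patient per group")
        for metric in METRICS:
            for agg in AGGREGATES:
                va = np.array([s.get(metric, agg) for s in group_a])
                vb = np.array([s.get(metric, agg) for s in group_b])
                res = mann_whitney_u(va, vb, method=method, unit_of_analysis="patient")
                rows.append(
                    {
                        "metric": metric,
                        "aggregate": agg,
                        "group_a_mean": float(va.mean()),
                        "group_b_mean": float(vb.mean()),
                        "u_statistic": res.statistic_value,
                        "p_value": res.p_value,
                        "n_a": res.n1,
                        "n_b": res.n2,
                    }
                )
    elif unit_of_analysis == "maneuver":
        if maneuver_table is None:
            raise ValueError("maneuver-level report needs the per-maneuver table")
        t = maneuver_table[maneuver_table["group"].isin(["A", "B"])]
        col_for = {
            "circumferential": "mean_circumferential",
            "anterior": "mean_anterior",
            "ratio": "ratio",
        }
        for metric in METRICS:
            col = col_for[metric]
            va = t.loc[t["group"] == "A", col].dropna().to_numpy()
            vb = t.loc[t["group"] == "B", col].dropna().to_numpy()
            if va.size == 0 or vb.size == 0:
                raise ValueError("need at least one maneuver per group")
            res = mann_whitney_u(va, vb, method=method, unit_of_analysis="maneuver")
            rows.append(
                {
                    "metric": metric,
                    "aggregate": "per-maneuver",
                    "group_a_mean": float(va.mean()),
                    "group_b_mean": float(vb.mean()),
                    "u_statistic": res.statistic_value,
                    "p_value": res.p_value,
                    "n_a": res.n1,
                    "n_b": res.n2,
                }
            )
    else:
        raise ValueError(f"unknown unit_of_analysis {unit_of_analysis!r}")

    table = pd.DataFrame(rows)
    if holm:
        table["p_holm"] = holm_adjust(table["p_value"].to_numpy())
    return GroupComparisonReport(table=table, unit_of_analysis=unit_of_analysis)


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def constipation_comparison(
    patients: Iterable[PatientRecord | PatientSummary],
    yates: bool = False,
) -> TestResult:
    """Group x constipation 2x2 chi-square.

    Accepts patient records or summaries (anything with ``group_label``
    and ``constipated``).  Patients with an unknown flag or group are
    excluded and the exclusion count reported as a finding.  The 2x2
    table (rows = groups A/B, columns = constipated yes/no) travels in
    ``extra["table"]``.
    """
    counts = {("A", True): 0, ("A", False): 0, ("B", True): 0, ("B", False): 0}
    excluded = 0
    for p in patients:
        group = p.group_label
        flag = p.constipated
        if group not in ("A", "B") or flag is None:
            excluded += 1
            continue
        counts[(group, bool(flag))] += 1
    table = [
        [counts[("A", True)], counts[("A", False)]],
        [counts[("B", True)], counts[("B", False)]],
    ]
    result = chi_square_2x2(table, yates=yates)
    findings = list(result.findings)
    if excluded:
        findings.append(
            Finding("warning", "excluded-patients", f"{excluded} patient(s) with unknown group or constipation flag excluded")
        )
    extra = dict(result.extra)
    n_a = counts[("A", True)] + counts[("A", False)]
    n_b = counts[("B", True)] + counts[("B", False)]
    extra["rate_a"] = counts[("A", True)] / n_a if n_a else None
    extra["rate_b"] = counts[("B", True)] / n_b if n_b else None
    extra["excluded"] = excluded
    return TestResult(
        statistic_name=result.statistic_name,
        statistic_value=result.statistic_value,
        p_value=result.p_value,
        df=result.df,
        n1=result.n1,
        n2=result.n2,
        unit_of_analysis="patient",
        method=result.method,
        extra=extra,
        findings=tuple(findings),
    )
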