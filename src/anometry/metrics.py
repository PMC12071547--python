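"""High-pressure-zone metrics for pull-through maneuvers.

For each maneuver the high-pressure zone (HPZ) is the axial level whose
moving-average-smoothed 8-channel mean pressure is maximal; smoothing is
used for localisation only, and the *raw* channel pressures at that level
are reported.  From the 8 raw values we compute the circumferential mean,
the anterior mean (channels 1, 2, 8) and their ratio — the quantity that
probes whether sphincter muscle is present anterior to the anal canal.
Per patient, at most the first six maneuvers (acquisition order) enter the
min/mean/max aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ANTERIOR_INDICES
from .io import Finding, PatientRecord, PullThroughRecording

MAX_MANEUVERS = 6  # analysis cap per patient

METRICS = ("circumferential", "anterior", "ratio")
AGGREGATES = ("min", "mean", "max")


class MetricsError(ValueError):
    """Raised when a maneuver or patient cannot yield valid metrics."""


@dataclass(frozen=True)
class ManeuverMetrics:
    """Per-maneuver HPZ pressures; ``ratio`` is None when undefined."""

    patient_id: str
    maneuver_id: int
    hpz_index: int
    hpz_axial: float  # cm
    circumferential_pressures: tuple[float, ...]  # 8 raw mmHg values at HPZ
    mean_circumferential: float
    mean_anterior: float
    ratio: float | None

    @property
    def valid(self) -> bool:
        return self.ratio is not None


@dataclass(frozen=True)
class AggregateTriple:
    min: float
    mean: float
    max: float


@dataclass(frozen=True)
class PatientSummary:
    """Min/mean/max of each metric across the patient's used maneuvers."""

    patient_id: str
    n_maneuvers_used: int
    n_maneuvers_dropped: int
    circumferential: AggregateTriple
    anterior: AggregateTriple
    ratio: AggregateTriple
    group_label: str = "unknown"
    constipated: bool | None = None

    def get(self, metric: str, aggregate: str) -> float:
        if metric not in METRICS:
            raise KeyError(f"unknown metric {metric!r}")
        if aggregate not in AGGREGATES:
            raise KeyError(f"unknown aggregate {aggregate!r}")
        return getattr(getattr(self, metric), aggregate)


def smoothed_channel_mean(recording: PullThroughRecording, smoothing_window: int = 3) -> np.ndarray:
    """Moving average of the 8-channel mean; the window truncates at the edges."""
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError(f"smoothing_window must be odd and >= 1, got {smoothing_window}")
    mean = recording.pressures.mean(axis=1)
    if smoothing_window == 1:
        return mean
    n = mean.size
    half = smoothing_window // 2
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, n)
    hi = np.clip(idx + half + 1, 0, n)
    csum = np.concatenate([[0.0], np.cumsum(mean)])
    return (csum[hi] - csum[lo]) / (hi - lo)


def detect_high_pressure_zone(
    recording: PullThroughRecording, smoothing_window: int = 3
) -> int:
    """Sample index of the HPZ (maximal smoothed 8-channel mean).

    Ties break toward the rectal side, i.e. the earliest sample; with at
    least 3 samples required.
    """
    if recording.n_samples < 3:
        raise MetricsError(
            f"recording {recording.patient_id}/{recording.maneuver_id} has "
            f"{recording.n_samples} samples (< 3)"
        )
    smoothed = smoothed_channel_mean(recording, smoothing_window)
    return int(np.argmax(smoothed))  # argmax returns the first maximum


def maneuver_metrics(
    recording: PullThroughRecording, smoothing_window: int = 3
) -> ManeuverMetrics:
    """Locate the HPZ and compute the circumferential/anterior means and ratio.

    The raw (unsmoothed) pressures at the HPZ feed the means.  A
    non-positive circumferential mean leaves ``ratio`` as None — a
    per-maneuver failure, not an exception.
    """
    idx = detect_high_pressure_zone(recording, smoothing_window)
    raw = recording.pressures[idx]
    mean_circ = float(raw.mean())
    mean_ant = float(raw[list(ANTERIOR_INDICES)].mean())
    ratio = mean_ant / mean_circ if mean_circ > 0 else None
    return ManeuverMetrics(
        patient_id=recording.patient_id,
        maneuver_id=recording.maneuver_id,
        hpz_index=idx,
        hpz_axial=float(recording.axial_positions[idx]),
        circumferential_pressures=tuple(float(v) for v in raw),
        mean_circumferential=mean_circ,
        mean_anterior=mean_ant,
        ratio=ratio,
    )


def aggregate_patient(
    metrics: list[ManeuverMetrics],
    patient_id: str,
    group_label: str = "unknown",
    constipated: bool | None = None,
    max_maneuvers: int = MAX_MANEUVERS,
    findings: list[Finding] | None = None,
) -> PatientSummary:
    """Min/mean/max of each metric over the first ``max_maneuvers`` maneuvers.

    Maneuvers with an undefined ratio are excluded from all three metrics
    and tallied as dropped (logged into ``findings`` when given).  Zero
    valid maneuvers raises :class:`MetricsError`.
    """
    if not metrics:
        raise MetricsError(f"patient {patient_id}: no maneuver metrics supplied")
    ordered = sorted(metrics, key=lambda m: m.maneuver_id)[:max_maneuvers]
    used = [m for m in ordered if m.valid]
    dropped = len(ordered) - len(used)
    if dropped and findings is not None:
        findings.append(
            Finding(
                "warning",
                "dropped-maneuvers",
                f"{dropped} maneuver(s) with undefined ratio excluded",
                patient_id,
            )
        )
    if not used:
        raise MetricsError(f"patient {patient_id}: no maneuver with a defined ratio")

    def triple(values: list[float]) -> AggregateTriple:
        arr = np.asarray(values, dtype=float)
        return AggregateTriple(float(arr.min()), float(arr.mean()), float(arr.max()))

    return PatientSummary(
        patient_id=patient_id,
        n_maneuvers_used=len(used),
        n_maneuvers_dropped=dropped,
        circumferential=triple([m.mean_circumferential for m in used]),
        anterior=triple([m.mean_anterior for m in used]),
        ratio=triple([m.ratio for m in used]),
        group_label=group_label,
        constipated=constipated,
    )


def summarize_patient(
    patient: PatientRecord,
    smoothing_window: int = 3,
    max_maneuvers: int = MAX_MANEUVERS,
    findings: list[Finding] | None = None,
) -> PatientSummary:
    """Convenience: per-maneuver metrics + aggregation for one patient record."""
    metrics = [
        maneuver_metrics(rec, smoothing_window)
        for rec in sorted(patient.recordings, key=lambda r: r.maneuver_id)
    ]
    return aggregate_patient(
        metrics,
        patient.patient_id,
        group_label=patient.group_label,
        constipated=patient.constipated,
        max_maneuvers=max_maneuvers,
        findings=findings,
    )
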