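"""Interchange format for pull-through recordings and cohort metadata.

A cohort on disk is a directory with two files:

``recordings.csv``
    Long-format samples, one row per (patient, maneuver, sample, channel):
    ``patient_id, maneuver_id, sample_index, time_s, axial_cm, channel,
    pressure_mmHg``.  Channels are 1-based (1..8), RFC-4180 CSV, UTF-8,
    '.' decimal separator.

``cohort.json``
    Sidecar with the format version, per-patient labels (group,
    constipation, optional age/sex), per-maneuver acquisition parameters
    and an echo of the simulation config when the cohort is synthetic.

The axial coordinate is 0 at the anal verge, positive toward the rectum;
a pull-through therefore has strictly *decreasing* axial positions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .geometry import CHANNEL_ANGLES_DEG, N_CHANNELS, angles_cover_circle

FORMAT_VERSION = "1.0"

CSV_COLUMNS = [
    "patient_id",
    "maneuver_id",
    "sample_index",
    "time_s",
    "axial_cm",
    "channel",
    "pressure_mmHg",
]

#: Physiologically implausible pressures flagged as warnings (mmHg).
PRESSURE_WARN_LOW = -5.0
PRESSURE_WARN_HIGH = 300.0


class CohortFormatError(ValueError):
    """Raised when on-disk cohort files violate the interchange format."""


@dataclass(frozen=True)
class Finding:
    """One machine-readable validation finding (never an exception)."""

    level: str  # "error" | "warning"
    code: str
    message: str
    patient_id: str | None = None
    maneuver_id: int | None = None


@dataclass
class PullThroughRecording:
    """A single pull-through maneuver: samples x 8 radial pressures.

    ``axial_positions`` are in cm (0 at the anal verge, positive rectal,
    strictly decreasing during the pull); ``pressures`` in mmHg.
    """

    patient_id: str
    maneuver_id: int
    axial_positions: np.ndarray
    pressures: np.ndarray
    channel_angles: np.ndarray = field(
        default_factory=lambda: CHANNEL_ANGLES_DEG.copy()
    )
    pull_speed: float = 1.0  # cm/s
    sampling_rate: float = 10.0  # samples/s

    def __post_init__(self) -> None:
        self.axial_positions = np.asarray(self.axial_positions, dtype=float)
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.channel_angles = np.asarray(self.channel_angles, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.pressures.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class PatientRecord:
    patient_id: str
    recordings: list[PullThroughRecording]
    group_label: str = "unknown"  # "A" | "B" | "unknown"
    constipated: bool | None = None
    age_months: float | None = None
    sex: str | None = None


@dataclass
class Cohort:
    patients: list[PatientRecord]
    config: dict[str, Any] | None = None

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)


def validate_recording(recording: PullThroughRecording) -> list[Finding]:
    """Check a recording against the format invariants.

    Returns findings instead of raising: ``error``-level findings are the
    corruptions :func:`read_cohort` refuses to load; ``warning``-level
    findings flag implausible but loadable data (pressures below -5 or
    above 300 mmHg).
    """
    pid, mid = recording.patient_id, recording.maneuver_id
    findings: list[Finding] = []
    p = recording.pressures

    if p.ndim != 2 or p.shape[1] != N_CHANNELS:
        findings.append(
            Finding(
                "error",
                "channel-count",
                f"expected {N_CHANNELS} channels, got shape {p.shape}",
                pid,
                mid,
            )
        )
        return findings  # shape is wrong; further checks would be misleading
    if p.shape[0] < 3:
        findings.append(
            Finding("error", "too-short", f"only {p.shape[0]} samples (< 3)", pid, mid)
        )
    if recording.axial_positions.shape[0] != p.shape[0]:
        findings.append(
            Finding(
                "error",
                "axial-length",
                "axial_positions length does not match sample count",
                pid,
                mid,
            )
        )
    elif not np.all(np.diff(recording.axial_positions) < 0):
        findings.append(
            Finding(
                "error",
                "axial-order",
                "axial positions must strictly decrease (rectal to external)",
                pid,
                mid,
            )
        )
    if not np.all(np.isfinite(p)):
        findings.append(
            Finding("error", "non-finite", "non-finite pressure values", pid, mid)
        )
    if not angles_cover_circle(recording.channel_angles):
        findings.append(
            Finding(
                "error",
                "channel-angles",
                "channel angles are not a 45-degree-spaced ring",
                pid,
                mid,
            )
        )
    with np.errstate(invalid="ignore"):
        n_low = int(np.sum(p < PRESSURE_WARN_LOW))
        n_high = int(np.sum(p > PRESSURE_WARN_HIGH))
    if n_low:
        findings.append(
            Finding(
                "warning",
                "pressure-low",
                f"{n_low} sample(s) below {PRESSURE_WARN_LOW} mmHg",
                pid,
                mid,
            )
        )
    if n_high:
        findings.append(
            Finding(
                "warning",
                "pressure-high",
                f"{n_high} sample(s) above {PRESSURE_WARN_HIGH} mmHg",
                pid,
                mid,
            )
        )
    return findings


def validate_patient(patient: PatientRecord) -> list[Finding]:
    """Patient-level invariants: >=1 recording, maneuver ids 1..k unique."""
    findings: list[Finding] = []
    if not patient.recordings:
        findings.append(
            Finding("error", "no-recordings", "patient has no recordings", patient.patient_id)
        )
        return findings
    ids = sorted(r.maneuver_id for r in patient.recordings)
    if ids != list(range(1, len(ids) + 1)):
        findings.append(
            Finding(
                "error",
                "maneuver-ids",
                f"maneuver ids {ids} are not contiguous from 1",
                patient.patient_id,
            )
        )
    for rec in patient.recordings:
        findings.extend(validate_recording(rec))
    return findings


def _recording_rows(rec: PullThroughRecording) -> pd.DataFrame:
    n = rec.n_samples
    idx = np.arange(n)
    return pd.DataFrame(
        {
            "patient_id": np.repeat(rec.patient_id, n * N_CHANNELS),
            "maneuver_id": np.repeat(rec.maneuver_id, n * N_CHANNELS),
            "sample_index": np.repeat(idx, N_CHANNELS),
            "time_s": np.repeat(rec.times, N_CHANNELS),
            "axial_cm": np.repeat(rec.axial_positions, N_CHANNELS),
            "channel": np.tile(np.arange(1, N_CHANNELS + 1), n),
            "pressure_mmHg": rec.pressures.ravel(),
        }
    )


def write_cohort(cohort: Cohort, path: str | Path) -> tuple[Path, Path]:
    """Write a cohort to ``path`` (a directory, created if absent).

    Returns the (csv_path, json_path) pair.  The written files round-trip
    losslessly through :func:`read_cohort`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    csv_path = path / "recordings.csv"
    json_path = path / "cohort.json"

    frames = [
        _recording_rows(rec) for patient in cohort.patients for rec in patient.recordings
    ]
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=CSV_COLUMNS)
    table.to_csv(csv_path, index=False, float_format="%.17g")

    meta = {
        "format_version": FORMAT_VERSION,
        "config": cohort.config,
        "patients": [
            {
                "patient_id": p.patient_id,
                "group_label": p.group_label,
                "constipated": p.constipated,
                "age_months": p.age_months,
                "sex": p.sex,
                "maneuvers": [
                    {
                        "maneuver_id": r.maneuver_id,
                        "pull_speed": r.pull_speed,
                        "sampling_rate": r.sampling_rate,
                        "n_samples": r.n_samples,
                        "channel_angles": [float(a) for a in r.channel_angles],
                    }
                    for r in sorted(p.recordings, key=lambda r: r.maneuver_id)
                ],
            }
            for p in cohort.patients
        ],
    }
    json_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return csv_path, json_path


def _major_version(version: str) -> str:
    return str(version).split(".", 1)[0]


def read_cohort(path: str | Path) -> Cohort:
    """Read and validate a cohort directory written by :func:`write_cohort`.

    Raises :class:`CohortFormatError` on any error-level corruption
    (missing channels, non-monotone axial coordinates, NaN pressures,
    metadata/CSV mismatches, unknown major format version); never returns
    a partially-loaded cohort.
    """
    path = Path(path)
    csv_path = path / "recordings.csv"
    json_path = path / "cohort.json"
    if not csv_path.exists() or not json_path.exists():
        raise CohortFormatError(f"{path}: missing recordings.csv or cohort.json")

    try:
        meta = json.loads(json_path.read_text())
    except json.JSONDecodeError as exc:
        raise CohortFormatError(f"{json_path}: invalid JSON ({exc})") from exc
    version = meta.get("format_version", "")
    if _major_version(version) != _major_version(FORMAT_VERSION):
        raise CohortFormatError(
            f"unsupported format version {version!r} (reader speaks {FORMAT_VERSION})"
        )

    table = pd.read_csv(csv_path, dtype={"patient_id": str}, float_precision="round_trip")
    missing_cols = set(CSV_COLUMNS) - set(table.columns)
    if missing_cols:
        raise CohortFormatError(f"recordings.csv missing columns {sorted(missing_cols)}")

    meta_patients = {p["patient_id"]: p for p in meta.get("patients", [])}
    csv_patients = set() if table.empty else set(table["patient_id"].unique())
    if csv_patients - set(meta_patients):
        raise CohortFormatError(
            f"patients in CSV but not metadata: {sorted(csv_patients - set(meta_patients))}"
        )

    patients: list[PatientRecord] = []
    grouped = None if table.empty else dict(iter(table.groupby(["patient_id", "maneuver_id"])))
    for pid, pmeta in meta_patients.items():
        recordings = []
        for mmeta in pmeta.get("maneuvers", []):
            mid = int(mmeta["maneuver_id"])
            block = None if grouped is None else grouped.get((pid, mid))
            if block is None:
                raise CohortFormatError(f"patient {pid} maneuver {mid}: no CSV rows")
            recordings.append(_block_to_recording(pid, mid, block, mmeta))
        patient = PatientRecord(
            patient_id=pid,
            recordings=recordings,
            group_label=pmeta.get("group_label", "unknown"),
            constipated=pmeta.get("constipated"),
            age_months=pmeta.get("age_months"),
            sex=pmeta.get("sex"),
        )
        errors = [f for f in validate_patient(patient) if f.level == "error"]
        if errors:
            first = errors[0]
            raise CohortFormatError(
                f"patient {first.patient_id} maneuver {first.maneuver_id}: "
                f"{first.code}: {first.message}"
            )
        patients.append(patient)

    if grouped is not None:
        declared = {
            (pid, int(m["maneuver_id"]))
            for pid, pmeta in meta_patients.items()
            for m in pmeta.get("maneuvers", [])
        }
        extra = set(grouped) - declared
        if extra:
            pid, mid = sorted(extra)[0]
            raise CohortFormatError(
                f"patient {pid} maneuver {mid}: CSV rows not declared in metadata"
            )

    return Cohort(patients=patients, config=meta.get("config"))


def _block_to_recording(
    pid: str, mid: int, block: pd.DataFrame, mmeta: dict
) -> PullThroughRecording:
    n_samples = int(mmeta["n_samples"])
    if len(block) != n_samples * N_CHANNELS:
        raise CohortFormatError(
            f"patient {pid} maneuver {mid}: {len(block)} rows, "
            f"expected {n_samples * N_CHANNELS} (truncated or padded file)"
        )
    pivot = block.pivot_table(
        index="sample_index", columns="channel", values="pressure_mmHg", aggfunc="first"
    )
    expected_channels = list(range(1, N_CHANNELS + 1))
    if list(pivot.columns) != expected_channels:
        raise CohortFormatError(
            f"patient {pid} maneuver {mid}: channels {list(pivot.columns)}, "
            f"expected {expected_channels}"
        )
    if list(pivot.index) != list(range(n_samples)):
        raise CohortFormatError(
            f"patient {pid} maneuver {mid}: sample indices not contiguous from 0"
        )
    pressures = pivot.to_numpy(dtype=float)
    if np.isnan(pressures).any():
        raise CohortFormatError(f"patient {pid} maneuver {mid}: NaN pressure")
    axial = (
        block.drop_duplicates("sample_index")
        .sort_values("sample_index")["axial_cm"]
        .to_numpy(dtype=float)
    )
    return PullThroughRecording(
        patient_id=pid,
        maneuver_id=mid,
        axial_positions=axial,
        pressures=pressures,
        channel_angles=np.asarray(mmeta["channel_angles"], dtype=float),
        pull_speed=float(mmeta["pull_speed"]),
        sampling_rate=float(mmeta["sampling_rate"]),
    )


def findings_frame(findings: Iterable[Finding]) -> pd.DataFrame:
    """Tabulate findings for the findings.csv artifact."""
    return pd.DataFrame([dataclasses.asdict(f) for f in findings], columns=[
        "level", "code", "message", "patient_id", "maneuver_id",
    ])
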