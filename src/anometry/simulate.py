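"""Synthetic pull-through cohorts with a controllable anterior sphincter deficit.

The generator's world is a two-group cohort of infants examined for a
suspected anterior anus.  Each patient carries a fixed *sphincter phenotype*:
an axial Gaussian high-pressure zone whose angular profile may be depressed
over an anterior window.  The noise-free pressure field is

    P(z, theta) = baseline + A * exp(-(z - z0)^2 / (2 sigma^2)) * g(theta)
    g(theta)    = 1 - d * w(theta - theta0)

where ``w`` is a raised-cosine window of half-width ``h`` degrees
(w(0) = 1, w(+-h) = 0): a smooth anterior "gap" rather than a hard-edged
one.  ``d = 0`` is a fully circular sphincter; ``d = 1`` a complete
anterior absence at the window center.

A pull-through maneuver samples this field along the axial coordinate at
``pull_speed / sampling_rate`` cm per sample through 8 radial channels,
plus i.i.d. Gaussian sensor noise and, with small probability, a transient
all-channel agitation artifact (infants are not always at rest).

Group priors default to values whose closed-form expected mean anterior
pressures are 61.2 mmHg (group A, abnormal sphincter) and ~136.3 mmHg
(group B, normal sphincter), with enough spread that the groups overlap
slightly; constipation is Bernoulli per group (0.45 vs 0.15) and the
number of maneuvers per exam is 1 + Binomial(9, 7/18), mean 4.5 on 1..10.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import CHANNEL_ANGLES_DEG, wrap_angle
from .io import Cohort, PatientRecord, PullThroughRecording

__all__ = [
    "SphincterPhenotype",
    "PhenotypePrior",
    "SimulationConfig",
    "pressure_field",
    "sample_phenotype",
    "simulate_pullthrough",
    "simulate_cohort",
    "default_maneuver_probs",
]


@dataclass(frozen=True)
class SphincterPhenotype:
    """Generative parameters of one patient's axial x angular pressure field."""

    baseline_pressure: float  # mmHg, resting recto-luminal background
    peak_amplitude: float  # mmHg above baseline at the high-pressure zone
    axial_center: float  # cm, location of the sphincter complex
    axial_sigma: float  # cm, axial spread of the high-pressure zone
    anterior_deficit: float  # 0 = circular sphincter, 1 = complete anterior absence
    deficit_halfwidth: float = 90.0  # degrees, angular half-width of the gap
    angular_offset: float = 0.0  # degrees, gap center relative to anterior midline

    def __post_init__(self) -> None:
        if not 0.0 <= self.anterior_deficit <= 1.0:
            raise ValueError(f"anterior_deficit must be in [0,1], got {self.anterior_deficit}")
        if self.axial_sigma <= 0:
            raise ValueError("axial_sigma must be positive")
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be non-negative")
        if self.baseline_pressure < 0:
            raise ValueError("baseline_pressure must be non-negative")
        if not 0.0 < self.deficit_halfwidth <= 180.0:
            raise ValueError("deficit_halfwidth must be in (0, 180]")


def raised_cosine_window(phi_deg, halfwidth_deg: float):
    """w(phi) = 0.5 (1 + cos(pi phi / h)) for |phi| <= h, else 0."""
    phi = np.abs(wrap_angle(phi_deg))
    inside = phi <= halfwidth_deg
    return np.where(inside, 0.5 * (1.0 + np.cos(np.pi * phi / halfwidth_deg)), 0.0)


def pressure_field(phenotype: SphincterPhenotype, axial_position, angle_deg):
    """Noise-free pressure (mmHg) at axial position(s) (cm) and angle(s) (deg).

    Broadcasts over its array arguments; deterministic.
    """
    z = np.asarray(axial_position, dtype=float)
    g = 1.0 - phenotype.anterior_deficit * raised_cosine_window(
        np.asarray(angle_deg, dtype=float) - phenotype.angular_offset,
        phenotype.deficit_halfwidth,
    )
    axial = np.exp(-((z - phenotype.axial_center) ** 2) / (2.0 * phenotype.axial_sigma**2))
    out = phenotype.baseline_pressure + phenotype.peak_amplitude * axial * g
    return out if out.shape else float(out)


@dataclass(frozen=True)
class PhenotypePrior:
    """Independent per-field prior for one group's phenotypes.

    Gaussian (clipped to physical floors) for the continuous fields and a
    Beta distribution for the anterior deficit; half-width and angular
    offset are fixed values, not sampled.
    """

    baseline_mean: float = 20.0
    baseline_sd: float = 3.0
    amplitude_mean: float = 120.0
    amplitude_sd: float = 25.0
    center_mean: float = 1.5
    center_sd: float = 0.3
    sigma_mean: float = 0.8
    sigma_sd: float = 0.15
    deficit_alpha: float = 1.0
    deficit_beta: float = 1.0
    deficit_value: float | None = None  # pins the deficit (degenerate prior)
    deficit_halfwidth: float = 90.0
    angular_offset: float = 0.0

    def sample(self, rng: np.random.Generator) -> SphincterPhenotype:
        if self.deficit_value is not None:
            deficit = float(self.deficit_value)
        else:
            deficit = float(rng.beta(self.deficit_alpha, self.deficit_beta))
        return SphincterPhenotype(
            baseline_pressure=max(1.0, rng.normal(self.baseline_mean, self.baseline_sd)),
            peak_amplitude=max(5.0, rng.normal(self.amplitude_mean, self.amplitude_sd)),
            axial_center=rng.normal(self.center_mean, self.center_sd),
            axial_sigma=max(0.2, rng.normal(self.sigma_mean, self.sigma_sd)),
            anterior_deficit=deficit,
            deficit_halfwidth=self.deficit_halfwidth,
            angular_offset=self.angular_offset,
        )

    def degenerate(self) -> bool:
        """True when every field has all prior mass on one value."""
        return (
            self.baseline_sd == 0
            and self.amplitude_sd == 0
            and self.center_sd == 0
            and self.sigma_sd == 0
            and self.deficit_value is not None
        )


# Calibrated so E[mean anterior] = baseline + amplitude * (1 - 2/3 E[d]):
# group A: 20 + 103 * (1 - 2/3 * 0.900) = 61.2 mmHg
# group B: 20 + 130 * (1 - 2/3 * 0.158) ~ 136.3 mmHg
DEFAULT_PRIOR_A = PhenotypePrior(
    amplitude_mean=103.0, amplitude_sd=25.0, deficit_alpha=9.0, deficit_beta=1.0
)
DEFAULT_PRIOR_B = PhenotypePrior(
    amplitude_mean=130.0, amplitude_sd=30.0, deficit_alpha=1.5, deficit_beta=8.0
)


def default_maneuver_probs() -> np.ndarray:
    """P(counts 1..10) = shifted Binomial(9, 7/18); mean exactly 4.5."""
    k = np.arange(10)
    p = 7.0 / 18.0
    pmf = np.array([math.comb(9, i) for i in k], dtype=float) * p**k * (1 - p) ** (9 - k)
    return pmf / pmf.sum()


@dataclass
class SimulationConfig:
    """Everything the generator needs; one seed drives all randomness."""

    n_group_a: int = 12
    n_group_b: int = 26
    prior_a: PhenotypePrior = field(default_factory=lambda: DEFAULT_PRIOR_A)
    prior_b: PhenotypePrior = field(default_factory=lambda: DEFAULT_PRIOR_B)
    maneuver_probs: Sequence[float] = field(default_factory=default_maneuver_probs)
    pull_speed: float = 1.0  # cm/s
    pull_speed_jitter_sd: float = 0.0  # cm/s, off by default
    sampling_rate: float = 10.0  # samples/s -> 1 mm axial resolution
    span_start: float = 3.0  # cm rectal of the anal verge
    recording_span: float = 6.0  # cm of catheter travel
    noise_sd: float = 5.0  # mmHg per-sample sensor noise
    artifact_probability: float = 0.1  # per maneuver
    artifact_magnitude: float = 30.0  # mmHg
    artifact_duration_s: float = 0.4  # Gaussian sd of the bump, seconds
    constipation_prob_a: float = 0.45
    constipation_prob_b: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 0 or self.n_group_b < 0:
            raise ValueError("group sizes must be non-negative")
        if self.pull_speed <= 0 or self.sampling_rate <= 0 or self.recording_span <= 0:
            raise ValueError("pull_speed, sampling_rate and recording_span must be positive")
        probs = np.asarray(self.maneuver_probs, dtype=float)
        if probs.shape != (10,) or probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise ValueError("maneuver_probs must be 10 non-negative values summing to 1")
        for name in ("artifact_probability", "constipation_prob_a", "constipation_prob_b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.noise_sd < 0 or self.artifact_magnitude < 0 or self.pull_speed_jitter_sd < 0:
            raise ValueError("noise/artifact/jitter magnitudes must be non-negative")

    def prior_for(self, group: str) -> PhenotypePrior:
        if group == "A":
            return self.prior_a
        if group == "B":
            return self.prior_b
        raise ValueError(f"unknown group label {group!r} (expected 'A' or 'B')")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maneuver_probs"] = [float(p) for p in np.asarray(self.maneuver_probs)]
        return d


def sample_phenotype(
    config: SimulationConfig, group: str, rng: np.random.Generator
) -> SphincterPhenotype:
    """Draw one phenotype from the group's prior (reproducible given rng state)."""
    return config.prior_for(group).sample(rng)


def simulate_pullthrough(
    phenotype: SphincterPhenotype,
    config: SimulationConfig,
    rng: np.random.Generator,
    patient_id: str = "sim",
    maneuver_id: int = 1,
) -> PullThroughRecording:
    """Simulate one pull-through maneuver of the given phenotype.

    The catheter starts ``span_start`` cm rectal of the verge and is pulled
    outward over ``recording_span`` cm; each sample advances
    ``pull_speed / sampling_rate`` cm.  Warns (and still records) when the
    sphincter center lies outside the recorded span.
    """
    speed = config.pull_speed
    if config.pull_speed_jitter_sd > 0:
        speed = max(0.1, rng.normal(speed, config.pull_speed_jitter_sd))
    step = speed / config.sampling_rate
    n = int(round(config.recording_span / step)) + 1
    axial = config.span_start - step * np.arange(n)

    if not (axial.min() <= phenotype.axial_center <= axial.max()):
        warnings.warn(
            f"axial_center {phenotype.axial_center:.2f} cm outside recorded span "
            f"[{axial.min():.2f}, {axial.max():.2f}] cm",
            stacklevel=2,
        )

    pressures = pressure_field(phenotype, axial[:, None], CHANNEL_ANGLES_DEG[None, :])
    pressures = np.broadcast_to(pressures, (n, 8)).copy()
    if config.noise_sd > 0:
        pressures += rng.normal(0.0, config.noise_sd, size=(n, 8))
    if config.artifact_probability > 0 and rng.random() < config.artifact_probability:
        center = rng.uniform(0, n - 1)
        sd = max(config.artifact_duration_s * config.sampling_rate, 1.0)
        bump = config.artifact_magnitude * np.exp(
            -((np.arange(n) - center) ** 2) / (2.0 * sd**2)
        )
        pressures += bump[:, None]

    return PullThroughRecording(
        patient_id=patient_id,
        maneuver_id=maneuver_id,
        axial_positions=axial,
        pressures=pressures,
        channel_angles=CHANNEL_ANGLES_DEG.copy(),
        pull_speed=speed,
        sampling_rate=config.sampling_rate,
    )


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate the full two-group cohort.

    One phenotype per patient; the patient's maneuver count is drawn from
    ``maneuver_probs`` (support 1..10) and every maneuver re-records the
    same phenotype with fresh noise.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    probs = np.asarray(config.maneuver_probs, dtype=float)
    patients: list[PatientRecord] = []
    groups = [("A", config.n_group_a, config.constipation_prob_a),
              ("B", config.n_group_b, config.constipation_prob_b)]
    for group, n_patients, constip_p in groups:
        for i in range(n_patients):
            pid = f"{group}{i + 1:03d}"
            phenotype = sample_phenotype(config, group, rng)
            n_maneuvers = int(rng.choice(np.arange(1, 11), p=probs))
            recordings = [
                simulate_pullthrough(phenotype, config, rng, patient_id=pid, maneuver_id=m)
                for m in range(1, n_maneuvers + 1)
            ]
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    recordings=recordings,
                    group_label=group,
                    constipated=bool(rng.random() < constip_p),
                )
            )
    return Cohort(patients=patients, config=config.to_dict())
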