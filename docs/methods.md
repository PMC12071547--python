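# Methods

## The measurement model

A pull-through maneuver records pressures `P(z, θ)` over axial position
`z` (cm; 0 at the anal verge, positive toward the rectum, decreasing
during the pull) and catheter channel angle `θ` (degrees from the
anterior midline). The synthetic generator's noise-free field is

```
P(z, θ) = b + A · exp(−(z − z₀)² / (2σ²)) · g(θ)
g(θ)    = 1 − d · w(θ − θ₀)
w(φ)    = ½ (1 + cos(π φ / h))   for |φ| ≤ h, else 0
```

with baseline `b` (mmHg), peak amplitude `A` (mmHg), axial center `z₀`
(cm), axial spread `σ` (cm), anterior deficit `d ∈ [0, 1]`, window
half-width `h` (default 90°) and window center `θ₀` (default 0°, the
anterior midline). `d = 0` is a fully circular sphincter; `d = 1` removes
the sphincter term completely at the window center. The raised-cosine
window was chosen over a hard-edged sector because muscle borders do not
produce pressure cliffs; its support (±90°) keeps the posterior semicircle
untouched.

Channel geometry: channel 2 sits on the anterior midline, channels 1 and
8 at ±45°, channels 3–7 fill the posterior arc at 90°–270°. The anterior
trio (1, 2, 8) therefore spans a contiguous 135° anterior sector. With
`h = 90°`, `θ₀ = 0`, the angular means have the closed forms
`mean g(anterior) = 1 − 2d/3` and `mean g(all 8) = 1 − d/4`, which the
pipeline-recovery tests use as an independent oracle.

## Metric extraction

- **HPZ localisation** maximises the moving-average-smoothed 8-channel
  mean (window 3 samples, edge-truncated, implemented by cumulative sums
  so it stays exact when the window exceeds the recording). Ties break
  toward the rectal side — the first maximum encountered during the pull.
  Smoothing is for localisation only; the **raw** channel pressures at
  the chosen index feed the metrics, preserving what a clinician would
  read off the trace.
- **Ratio** `r = mean(anterior) / mean(all)` is undefined when the
  circumferential mean is ≤ 0; such maneuvers are dropped from the
  patient's aggregation (with a logged finding), never zero-filled.
- **Aggregation** uses at most the first six maneuvers in acquisition
  order and reports min/mean/max per metric. Each recording is analysed
  independently (HPZ per maneuver, not once per exam).

## The classifier

Abnormal ⇔ mean anterior pressure < 75 mmHg AND mean ratio < 0.7, both
strict comparisons; OR-combination and min/max aggregates are config
options. Group A (abnormal sphincter on the reference standard) is
condition positive. Sensitivity and specificity carry exact two-sided
Clopper–Pearson intervals (beta-quantile form, closed ends at k = 0 and
k = n); exactness over a binomial-tail root-finding oracle and interval
conservativeness (coverage ≥ nominal) are both tested. The threshold
sweep evaluates a grid of (anterior, ratio) thresholds — 0 and +∞ are
legal grid points so the flag-nobody / flag-everybody corners are
expressible — and reports the best Youden point.

## Statistics

- **Mann–Whitney U**: midranks for ties; `U₁ = R₁ − n₁(n₁+1)/2`; the
  reported statistic is min(U₁, U₂). The default p-value is exact while
  `n₁·n₂ ≤ 400` — a dynamic programme over tie groups enumerates the full
  permutation distribution of U, equivalent to brute-force enumeration of
  all C(n, n₁) assignments but feasible at these sizes — and otherwise the
  tie-corrected normal approximation without continuity correction
  (`σ² = n₁n₂/12 · [(n+1) − Σ(t³−t)/(n(n−1))]`). A fully tied pooled
  sample has σ = 0; p is then 1 by convention. The two conventions agree
  to < 0.01 wherever the exact p ≤ 0.1; near the null center the discrete
  point mass makes the exact p up to ≈ 0.046 larger at n₁ = n₂ = 8
  (verified by complete enumeration), so borderline mid-range p-values
  should be read with that in mind.
- **Chi-square (2×2)**: Pearson closed form with df = 1, optional Yates
  correction; a zero marginal yields an undefined-statistic finding
  rather than an exception, and expected cells < 5 raise a small-count
  warning.
- **Group report**: 3 metrics × min/mean/max = 9 rows, group means being
  arithmetic means of per-patient aggregates. The unit of analysis is
  the patient by default; a per-maneuver mode exists because published
  U values of this study design sometimes imply maneuver-level counts.
  Raw p-values are reported (an optional Holm adjustment is off by
  default, matching how such tables are conventionally published).

## Synthetic cohort calibration

Group priors (independent per field; Gaussians clipped to physical
floors, Beta for the deficit):

| parameter | group A (abnormal) | group B (normal) |
|---|---|---|
| baseline b | N(20, 3) mmHg | N(20, 3) mmHg |
| amplitude A | N(103, 25) mmHg | N(130, 30) mmHg |
| axial center z₀ | N(1.5, 0.3) cm | same |
| axial spread σ | N(0.8, 0.15) cm | same |
| deficit d | Beta(9, 1), mean 0.90 | Beta(1.5, 8), mean 0.158 |

These were set analytically, not by fitting: the expected mean anterior
pressure is `E[b] + E[A]·(1 − ⅔·E[d])`, giving 61.2 mmHg for group A and
≈136.3 mmHg for group B — the cohort contrast the generator is meant to
emulate — with spreads wide enough that the groups overlap and the
cut-off rule stays imperfect (sensitivity ≈ 0.8 at scale). The implied
group B ratio (≈0.94) and circumferential mean (≈145 mmHg) land close to
the emulated study's values without separate tuning.

Acquisition defaults: pull 1 cm/s sampled at 10 Hz (1 mm axial
resolution — fine enough that peak discretisation error is far below the
noise), span 6 cm starting 3 cm rectal of the verge (comfortably contains
an infant sphincter complex), per-sample Gaussian sensor noise
sd 5 mmHg, and with probability 0.1 per maneuver a transient all-channel
positive bump (30 mmHg, Gaussian time profile, sd 0.4 s) emulating
agitation. Pull-speed jitter exists as a knob but is off by default.
Maneuver counts are 1 + Binomial(9, 7/18) (support 1–10, mean exactly
4.5); constipation is Bernoulli(0.45 / 0.15) per group. One seed drives a
single `numpy` generator through phenotypes, maneuver counts, noise,
artifacts and labels, so cohorts serialize byte-identically across runs.

**What the generator does not emulate:** between-maneuver phenotype drift
within a patient (only sensor noise varies across a patient's maneuvers),
skewed or heavy-tailed pressure distributions, correlated channel noise,
catheter rotation between maneuvers, RAIR or squeeze responses, and any
real link between sphincter anatomy and constipation (flags are sampled
independently of the phenotype). A green recovery test therefore
establishes that the pipeline inverts *this* generative model, not that
it would match any particular clinical data set.

## Numerical choices and degenerate inputs

- HPZ ties break to the earliest (most rectal) sample; the constant
  recording returns index 0.
- Recordings shorter than 3 samples are a maneuver-level failure; a
  patient with no valid maneuver is a patient-level failure; both surface
  as findings while the rest of the cohort is analysed.
- Clopper–Pearson at k = 0 / k = n closes the interval at 0 / 1.
- CSV round-trips are bit-exact: writing uses 17 significant digits and
  reading uses the round-trip float parser.
- The interchange reader refuses (rather than partially loads) cohorts
  with missing channels, non-monotone axial coordinates, NaN pressures,
  CSV/metadata mismatches, or an unknown major format version.

## Known limitations

- The per-patient min/mean/max aggregates of a metric are correlated, so
  the 9 comparison rows are not independent tests; no multiplicity
  adjustment is applied by default.
- The exact Mann–Whitney enumeration is limited to n₁·n₂ ≤ 400 by
  default; beyond that the normal approximation is used automatically.
- Diagnostic-accuracy CIs treat patients as independent; repeated exams
  of one child would violate that.
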