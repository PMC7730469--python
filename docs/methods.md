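# Methods

## Scope and data model

The package analyzes single-sensor heel IMU recordings of a prolonged
(nominally 60-min) treadmill brisk-walking bout. A recording is nine
uniformly sampled channels at 50 Hz: linear acceleration (±16 g full
scale), angular velocity (±2000 °/s), and fused orientation angles
(x/z in (−180°, 180°], y in [−90°, 90°)), with x = medial–lateral,
y = anterior–posterior, z = vertical. Orientation channels are treated as
given inputs (the device's own sensor fusion produces them); no inertial
fusion is re-implemented here.

The repeated-measures design compares three 60-s windows — the baseline
(first), 30th, and 60th minutes, i.e. samples
[0, 3000), [87000, 90000), [177000, 180000) — within subject. Windows are
half-open sample ranges `[round(start·fs), round(end·fs))`; all indexing
in the package is 0-based and half-open. The baseline analysis minute
overlaps the 30-s orientation-calibration span; nothing in the protocol
requires excluding it, so no exclusion is applied.

## Baseline-relative orientation

The mean orientation over the first 30 s of walking is subtracted from
each angle channel. For the ±180° channels (gx, gz) the circular mean
(atan2 of averaged sin/cos) is used so a trace hovering near ±180° does
not corrupt the reference, and differences are wrapped back to
(−180°, 180°]. The y angle is range-limited to ±90° and cannot wrap, so
it uses the arithmetic mean, with results wrapped to [−90°, 90°). The
operation is invariant to adding any constant (wrapped) offset to an
angle channel.

## Gait-cycle segmentation

The study design counts outcomes per gait cycle but does not fix a
detection algorithm, so the package isolates one behind the
`segmentation` interface: heel strikes are local maxima of the
medial–lateral angular velocity (wx) — the sensor sits on the posterior
heel and the sagittal-plane rotation spike just after initial contact is
the standard IMU landmark — exceeding an adaptive prominence threshold
of 0.5 × (90th percentile of |wx| in the window), separated by at least
`min_cycle_s`. The percentile rule tracks amplitude drift over the hour
without per-subject tuning. Peaks within one `min_cycle_s` of a window
edge have flank-truncated prominence, so a second pass accepts near-edge
local maxima reaching 70% of the median interior peak height; without it
every window systematically loses its edge cycles.

A cycle is the half-open span between consecutive detected strikes of
the instrumented foot; the partial segments before the first and after
the last strike are dropped ("incomplete cycles ignored"), and candidate
cycles outside [0.6 s, 2.5 s] — bracketing the ~1 s cycles of elderly
brisk walking at ~3.9 km/h — are discarded. No stance/swing decomposition
is attempted. Fewer than two detected strikes yields an empty cycle list,
which downstream stages treat as a flagged, logged data-quality exclusion
rather than an error.

## Per-cycle statistics

Ten statistics per channel and cycle: MAD (median of |x − median x|),
excess kurtosis (m₄/m₂² − 3), skewness (m₃/m₂^{3/2}), RMS (√mean x²),
variance, max |x|, min |x|, range (max x − min x of the signed signal),
median |x|, and EC — signal power, the finite-support evaluation of the
limiting power integral as the mean of squared samples over the cycle.
All moment statistics use population (divide-by-n) conventions, making
EC = RMS² an exact per-cycle identity; note the window *means* of EC and
RMS² do not coincide (cycles with RMS {1, 3} average to mean RMS 2 but
mean EC 5). Whether the original analysis used bias-corrected sample
moments is unknowable, so a `biased=False` switch provides the corrected
kurtosis/skewness for sensitivity checks; the default is the population
form. Zero-variance cycles define kurtosis and skewness as 0 (logged)
rather than 0/0. Skewness and kurtosis are computed from deviations
normalized by their maximum — they are scale-free, and this keeps the
moment ratios finite for arbitrarily tiny or huge signals.

Window aggregation is the arithmetic mean over complete cycles; each
subject's window aggregates are divided by that subject's baseline
aggregates, so every outcome is a unitless ratio with baseline ≡ 1 and
between-subject scale differences cancel before any cohort statistics.
A zero baseline aggregate marks the (channel, feature) as missing (NaN,
logged), never infinity; a window with no cycles flags the whole
subject-window. Missing entries exclude the subject listwise from the
affected block only.

## Statistical battery

Per (channel, feature) block the cohort forms an n×3 matrix of ratios
(baseline column ≡ 1). Shapiro–Wilk W and p for the min30/min60 columns
are recorded as diagnostics justifying the nonparametric path; they never
gate computation. The omnibus test is the tie-corrected Friedman
chi-square form,

Q = (k−1) Σⱼ (Rⱼ − n(k+1)/2)² / (Σᵢⱼ rᵢⱼ² − nk(k+1)²/4),  k = 3,

with average ranks within rows (the constant baseline column ties
harmlessly) and p from χ²(k−1). An exact permutation null — dynamic
programming over all 6ⁿ within-row rank permutations — is available via
`method="exact"` for small cohorts without within-row ties. Post hoc,
only omnibus-significant blocks (α = 0.05) receive the three pairwise
Wilcoxon signed-rank contrasts; the gating is on the omnibus alone, so a
significant block can show no starred contrast. Zero differences are
discarded before ranking (Wilcoxon's rule; count logged), the exact null
of the positive-rank sum is used for n ≤ 25 (computed by convolution
over doubled average ranks — identical to enumerating all 2ⁿ sign
assignments, and valid under ties), and a tie-corrected normal
approximation without continuity correction beyond. Bonferroni adjusts
each raw p to min(1, 3p), equivalently testing raw p against
0.05/3 ≈ 0.017. Adjusted values are computed from unrounded raw p-values.
No correction is applied across the 90 omnibus tests, mirroring the
original design; this multiplicity caveat means ~4–5 false-positive
blocks are expected under the global null at α = 0.05.

**Discreteness caveat.** With n = 18 subjects and k = 3 conditions the
Friedman rank statistic is discrete: the attainable significance levels
nearest 0.05 are ≈0.0552 (Q ≥ 5.778) and ≈0.0448 (Q ≥ 6.333), for the
exact and the χ²-approximated test alike (the suite computes this from
the exact null). No valid rank test of this design can have size exactly
0.05; simulated null rejection rates settle near 0.045, and the
calibration test documents this measured gap.

## Synthetic cohorts

The simulator emulates the study conditions — 18 elderly subjects,
60-min bouts at 50 Hz, stride rates drawn uniformly from 0.8–1.1 Hz
(brisk walking near 3.9 km/h) — while keeping ground truth analytic.
Each channel's cycle waveform is a sum of 3–5 harmonics of the cycle
frequency with amplitudes mimicking heel kinematics (dominant wx spike
just after heel strike, 1 g gravity offset on az, small constant offsets
on the angles); a per-subject lognormal amplitude gain (CV 0.1) adds
between-subject heterogeneity that cancels in the normalized ratios.
Cycle durations are T·lognormal(0, cv) with cv = 0.03 by default,
rounded to whole samples so that a jitter-free configuration has a
bit-identical sample grid every cycle (the rounding quantizes jitter at
20 ms). White Gaussian noise (defaults 0.05 g, 5 °/s, 0.5°) is added,
then values are clipped/wrapped to the device ranges. The wx peak sits
4% of a cycle after the strike so that strikes at window edges remain
detectable local maxima and detected boundaries fall within ±2 samples
of truth.

Fatigue effects are per-channel multipliers on template amplitude,
template offset, or duration-jitter scale. A multiplier holds at 1
across the baseline window, ramps linearly in time between windows, and
holds at its configured target across the 30th- and 60th-minute windows:
each analysis window therefore sits exactly at its nominal effect level,
which is what makes noiseless parameter recovery exact. The published
results report only the directions of significant changes, not effect
sizes, so `default_fatigue_effects()` encodes directions with modest
plausible magnitudes (strongest on the vertical rotation angle, the
pronation-drift signature) and is used only in examples and power runs —
it is not a claim about true effect sizes.

What the simulator does *not* model: musculoskeletal dynamics, the
treadmill speed ramp, sensor-fusion drift or bias instability,
non-stationary noise, missed-contact artifacts, or asymmetry between
feet. Passing recovery tests therefore demonstrates the correctness of
the pipeline's bookkeeping and statistics under a known generative
model, not validity of any fatigue claim on real cohorts.

## Numerical and design choices

- Deterministic recovery checks use cadence 1.0 Hz, zero jitter, zero
  noise: 50 samples per cycle and exactly 30 cycles in the orientation
  baseline make the recovered amplitude ratio exact to ~1e-8. At
  non-divisor cadences the partial cycle inside the 30-s orientation
  span leaves a ~1e-5-relative residual in the angle ratios — a property
  of the baseline-rebasing step, documented rather than hidden.
- Simulation-heavy checks (null calibration) use 3-minute bouts with
  windows at minutes 1/2/3: under the null the process is stationary, so
  window placement does not change the ratio distribution, and 500
  cohorts stay tractable. Effect-recovery runs keep the full 60-min
  design.
- Ties: average ranks everywhere; fully tied Friedman rows give Q = 0,
  p = 1; an all-zero-difference Wilcoxon contrast is degenerate and
  reported as p = 1 with a flag.
- CSV dialect: comma-separated, UTF-8, '.' decimal, header
  `time_s,ax_g,ay_g,az_g,wx_dps,wy_dps,wz_dps,gx_deg,gy_deg,gz_deg`;
  unparsable rows are dropped with logged line numbers; a >10% mismatch
  between the median timestamp interval and 1/fs is an error.
- The published omnibus and post hoc tables of the original cohort are
  shipped as fixed reference data (`gaitfatigue.reference`) because the
  raw recordings were never deposited; only deterministic arithmetic on
  them (the α filter, the Bonferroni map) is reproduced. Post hoc rows
  like raw 0.016 → adjusted 0.049 were evidently adjusted from unrounded
  raw values; the self-consistent pairs are listed separately.

## Known limitations

Heel-strike detection is an implementation choice the source protocol
leaves open; alternative landmarks (acceleration peaks, gyro zero
crossings) would shift cycle boundaries by a constant few samples.
Window-level aggregates are sensitive to the handful of cycles at window
edges. The battery inherits the discreteness limits of rank tests at
n = 18, and the uncorrected 90-test omnibus family inflates the
family-wise error rate by design fidelity to the original analysis.
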