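# Methods

This note documents the models, estimators and numerical choices behind
`lcpupil`, in the spirit of a statistics package's model documentation.
Nothing here asserts an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and conventions

All times are seconds from session start. Pupil traces are regularly
sampled (20–50 Hz typical) with interval-start timestamps; values are mm
(raw) or z (session z-scored, sample SD with n−1). Interchange files are
plain CSV with a header row; NWB-style containers are deliberately out of
scope. On reading, timestamps jittered by less than half a sample period
are snapped to the declared grid; missing or NaN samples (blinks, tracking
losses) are linearly interpolated up to 1-s gaps, and longer gaps raise —
`split_on_gaps` produces per-segment traces instead. The 1-s limit and the
interpolation rule are this package's choice; upstream acquisition
pipelines rarely document theirs.

## Spike clustering

Two adjacent spikes belong to one cluster when their ISI is *strictly*
shorter than the threshold, which defaults to the unit's per-session
median ISI; ties split (the wording "shorter than" reads as strict). A
single spike is a valid cluster of size 1; cluster onset is its first
spike. The clustering partitions the train, the cluster count is
non-increasing in the threshold, and `cluster_sensitivity` reports the
size distribution across thresholds (0.1–0.5 s) for robustness checks.
Trial boundaries are ignored at this stage.

## Pupil preprocessing and dilation events

Order of operations: z-score over the whole session → 500-ms centered
moving average (odd sample count, shrinking windows at the edges) →
slopes as finite differences of consecutive 200-ms bin means. A dilation
event is the maximum trace value between sequential positive
zero-crossings (slope ≤ 0 → > 0) of the slope series; its amplitude is
that value in session-SD units (not peak-minus-trough), which is what the
0.3-SD binning presumes. A local linear fit per 200-ms bin instead of the
binned finite difference gives indistinguishable events on synthetic data;
the finite difference is kept for simplicity. Events with amplitude < 0
(maxima below the session mean) are retained but fall outside the 0–3 SD
bins and are only counted in the overflow report.

## Forward and reverse coupling

The triggered "peak pupil dilation" is the signed maximum of the z-scored
trace in [onset, onset + 6 s] — a deep constriction is not a dilation peak.
An `peak_mode="absolute"` switch implements the max-|z| reading instead.
Responses whose window leaves the recording are excluded. The session
slope is fit two ways: per-size mean peaks (`fit_linear`, mirroring the
classic presentation and its ≥3-distinct-sizes requirement) and per
response (`fit_linear_responses`), which has enough degrees of freedom for
a stable slope standard error and is what the pipeline reports.

The pre-event spike window is half-open, [t−4, t−2): the −4 s bound is in,
the −2 s bound is out, avoiding double counting at bin edges. Lick
exclusion removes clusters whose *onset* lies within the closed interval
±0.5 s of any lick.

## Ideal observer

`auc` is the midrank (Mann–Whitney) estimator, exactly antisymmetric and
equal to exhaustive pair counting with ties at ½ — necessary because spike
counts are small integers. Baseline draws are number-matched and repeated
(default 100, mean ± SD reported; the mean is insensitive to 50–200
repeats). Two baseline constructions exist:

* `"samples"` (default): single pupil samples drawn uniformly from the
  session — the literal "randomly selected pupil diameter".
* `"matched_peaks"`: window maxima at uniformly random onsets.

The distinction matters for calibration. The positive class is a
*maximum over a 6-s window*, which is stochastically larger than a single
sample even when spikes and pupil are independent; the sample baseline
therefore carries a selection bias of roughly +0.1 AUC at every condition,
and its null is not 0.5. The matched-peaks construction makes the two
classes exchangeable under zero coupling, so its null AUC is exactly 0.5;
all calibration and recovery checks use it, and the sample construction
remains available for descriptive use. d′ conversion assumes the
equal-variance Gaussian observer: AUC = Φ(d′/√2), so d′ = 1 ↔ 0.760
("~0.75"); the package uses 0.75 as the performance threshold.

## Resampling statistics

The session permutation test pools both sessions' per-trial evoked
responses and redraws pseudo-sessions of the original sizes *with
replacement* (as specified; a strict-permutation switch exists), two-sided
via the absolute mean difference, with the add-one correction
p = (1 + #{null ≥ obs})/(n + 1) so p is never 0. On exchangeable trials
the test is well calibrated (measured type-I 0.047 at α = 0.05). On fully
simulated session pairs it is mildly conservative (0.015–0.03): the
Ornstein–Uhlenbeck drift mean-reverts, so successive evoked responses are
negatively correlated and session means are under-dispersed relative to
the pooled null. It is never anti-conservative in these conditions.

Across-session variability resamples trials pooled over all sessions into
as many pseudo-sessions as real ones (each with the real session's trial
count) and averages the SD of pseudo-session means over 100 repeats.
"Within-session variability" is defined here as the bootstrap SD of each
session's mean, averaged over sessions — the natural same-units
comparator; the two agree within ±40% for exchangeable sessions and
separate sharply when true session means differ. The
`within_outside_5pct` flag compares each session's trial SD against the
central 95% of pooled-resample SDs. Baseline-matched session pairs use a
configurable |Δbaseline| ≤ 0.05 mm tolerance (the matched examples differ
by 0.04 mm; no explicit criterion is published).

## Behavior

Decision bias is the SDT criterion c = −(z(H) + z(FA))/2 with rates
clamped to [1/(2n), 1 − 1/(2n)] before the normal quantile; d′ = z(H) −
z(FA) with the same clamping. The criterion choice (rather than, say,
log-β) is conventional for Go/NoGo licking tasks and is exposed so another
index can be plugged in. Sessions enter slope–behavior correlations only
with >100 trials and per-size-mean R² > 0.6.

## Optical stimulation model

Irradiance under the fiber tip: I(z) = I(0)·ρ²/((Sz+1)(z+ρ)²) with
ρ = r·√((n/NA)² − 1) and I(0) = P/(πr²). Defaults: P = 10 mW, r = 0.1 mm
(200-µm core), NA = 0.39, n = 1.4, threshold 2.5 mW/mm², scattering
S = 11.2 mm⁻¹ (mouse cortical tissue — the one parameter the published
description leaves implicit), cone full angle 30° (interpreted as full
apex angle; half-angle 15°, configurable). The threshold depth z* is found
by bisection to 10⁻⁶ mm (oracle-checked against a fine-grid scan), and the
volume is the conical frustum from r to r + z*·tan 15°. With these
defaults z* = 0.853 mm and V = 0.135 mm³, at the upper end of the
published 0.05–0.1 mm³ order of magnitude; V scales with S and the cone
angle, both documented rather than asserted.

## Synthetic-data generator

The generator emulates the statistical structure the analyses rely on,
not pupil biophysics:

* **Spike train**: homogeneous Poisson cluster onsets (default 0.08 s⁻¹),
  geometric cluster sizes P(k) = p(1−p)^(k−1) with p = 0.55, fixed 40-ms
  intra-cluster ISIs. Geometric sizes reproduce a monotonically decaying
  occurrence with a single parameter. p must exceed 0.5 for median-ISI
  clustering to be meaningful on this pure burst process: below that,
  within-cluster ISIs are the majority and the median ISI equals the
  intra-burst ISI, so the strict-< rule splits every burst. At p = 0.55
  the median ISI lands in the gap region (≈1.2 s) and sizes ≥ 4 each occur
  in <10% of clusters.
* **Pupil**: value(t) = OU-drift + gain·Σᵢ kernel(t − tᵢ) + white noise at
  20 Hz. The kernel is gamma-shaped, k(t) ∝ t^a·e^(−t/θ), parameterised by
  peak latency (3 s, inside the 2.5–4 s range measured for pupil responses
  to LC spiking), decay (1 s) and amplitude (0.2 z/spike). OU drift
  (SD 0.7, τ = 30 s) stands in for slow spontaneous arousal fluctuations;
  white noise (SD 0.15) for measurement error.
* **Calibration**: with gain 1, the session slope is ≈0.20 z/spike (inside
  the 0.12–0.51 range reported for awake recordings) and the
  matched-peaks AUC crosses 0.75 at cluster size 5–6, whose occurrence is
  ~2–3% — the regime in which only infrequent strong bursts are decodable.
  These defaults were fixed from this calibration and are not adjusted
  per analysis.
* **Stimulated pairs**: each stimulation trial injects n_pulses spikes at
  the pulse frequency into the spontaneous train; evoked responses are
  baseline-subtracted window maxima. Configs of a pair may differ only in
  gain, noise and seed.
* **Behavior**: Bernoulli Go/NoGo outcomes at specified hit/FA rates,
  with licks placed at responses.

What the generator does **not** emulate: correlated multi-unit
populations (one ground-truth unit per session), luminance and saccade
artifacts, blinks, refractory/tonic spiking structure (spikes exist only
inside clusters), non-stationary gain within a session, and any pupil
constriction dynamics. Passing tests therefore demonstrate the
*estimators'* correctness and calibration on data with known ground
truth, not that real recordings satisfy the generative assumptions.

## Problem sizes and numerical choices

Test and acceptance runs use 1800–3600-s sessions (the scale of an
hour-long head-fixed recording), cohorts of 30–40 sessions for group
curves, 200 sessions for null calibration, and 400 pairs for type-I
estimates; these sizes put Monte-Carlo error comfortably inside the
asserted tolerances while keeping the whole suite at a few minutes on one
CPU. Null-calibration note: the "slope within 2·SE of 0" coverage is
P(|t_df| < 2) ≈ 95.2–95.45% depending on cluster count, which is why the
calibration uses hour-long sessions (df ≈ 290). Degenerate inputs are
defined errors: <3 spikes for a median ISI, <3 distinct cluster sizes for
a linear fit (such sessions are flagged, mirroring the exclusion of
recordings with limited cluster sizes), constant traces for z-scoring,
zero baselines for percent change and normalization. RNG is
`numpy.random.default_rng` throughout; every stochastic routine takes a
seed or Generator, and a given seed reproduces results bit-for-bit.
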