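# lcpupil

Analysis of the coupling between pupil diameter and locus coeruleus (LC)
spiking in paired awake recordings — for systems neuroscientists who want to
know how faithfully pupillometry reads out noradrenergic activity on a
moment-by-moment basis.

## What it computes

Pupil diameter under constant luminance tracks arousal, and the LC is its
presumed noradrenergic driver. This package implements both directions of
the question:

* **Forward (spikes → pupil).** Adjacent spikes are grouped into clusters
  whenever an interspike interval is shorter than the unit's median ISI.
  The peak z-scored pupil value in a 6-s window from each cluster onset,
  summarised per cluster size *k*, gives the coupling curve; its OLS slope
  (z-units per spike) is the session's coupling strength. Clusters within
  ±0.5 s of a lick can be excluded.
* **Reverse (pupil → spikes).** The trace is z-scored, smoothed (500 ms),
  and slopes are estimated every 200 ms; a dilation event is the pupil
  maximum between sequential positive zero-crossings of the slopes. LC
  spikes are counted in a −4 to −2 s pre-event window and events are
  binned every 0.3 SD of amplitude.
* **Ideal observer.** For a condition (cluster size or event bin) with
  values x and number-matched baseline draws y, AUC = P(x > y) + ½P(x = y)
  (Mann–Whitney form). The performance threshold d′ = 1 corresponds to
  AUC = Φ(1/√2) ≈ 0.76 for the equal-variance Gaussian observer.
* **Resampling statistics.** 100× percentile bootstrap for per-session
  means, a 1000-iteration with-replacement permutation test for paired
  optogenetic sessions, and pooled-resampling estimates of across- vs
  within-session variability.
* **Behavior.** Go/NoGo hit rate, false-alarm rate, and decision bias
  c = −(z(H) + z(FA))/2, correlated with per-session coupling slopes.
* **Optical stimulation.** Evoked pupil/spike responses, session
  normalization, and the excitable-volume estimate
  I(z) = I(0)·ρ²/((Sz+1)(z+ρ)²) with a conical-frustum volume down to the
  threshold depth.
* **Synthetic data.** A generator with known ground truth: Poisson cluster
  onsets, geometric cluster sizes, a gamma-shaped per-spike pupil kernel
  peaking at 3 s, Ornstein–Uhlenbeck drift, white noise, per-session gain,
  stimulation trials, and Go/NoGo sessions with controllable rates.

## Worked example

```python
import lcpupil as lp

cfg = lp.SimConfig(duration=1800.0, seed=42)
train, trace, _ = lp.generate_session(cfg)
fw = lp.forward_analysis(train, trace)
print(fw.curve.as_frame().round(3))
print(f"slope = {fw.slope:.3f} ± {fw.slope_se:.3f} z/spike")
```

prints

```
 size  mean_peak   sem  occurrence  n
    1      0.635 0.111       0.460 69
    2      0.859 0.142       0.260 39
    3      0.751 0.196       0.187 28
    4      1.480 0.250       0.040  6
    5      1.712 0.373       0.040  6
slope = 0.183 ± 0.063 z/spike
```

Mean peak pupil dilation grows with cluster size — each extra LC spike adds
≈0.2 SD of dilation — while the occurrence column shows large clusters are
rare. Running the ideal observer on such a session
(`examples/04_ideal_observer.py`) gives AUCs rising from 0.55 (size 1) to
0.88 (size 6), crossing the 0.75 (d′ = 1) threshold only at size ≥ 5,
i.e. for clusters that make up under 10% of LC activity: pupil dilation is
a reliable real-time readout only of infrequent, strong LC bursts.

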