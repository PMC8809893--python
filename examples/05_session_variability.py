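"""Session-to-session variability of evoked pupil responses.

Two sessions receive the identical optical stimulation schedule (four
10-ms pulses at 10 Hz per trial). Per-session means get a 100x percentile
bootstrap CI; the with-replacement permutation test (1000 iterations)
asks whether the sessions differ; pooled resampling compares across- vs
within-session variability.
"""
import lcpupil as lp

stim = lp.make_stim_table(30, iti=15.0, n_pulses=4, freq_hz=10.0)
dur = 30 * 15 + 40.0

same = lp.generate_session_pair(
    lp.SimConfig(duration=dur, seed=1), lp.SimConfig(duration=dur, seed=2), stim
)
diff = lp.generate_session_pair(
    lp.SimConfig(duration=dur, gain=1.0, seed=3),
    lp.SimConfig(duration=dur, gain=2.5, seed=4),
    stim,
)

for label, pair in [("same gain", same), ("gain 1.0 vs 2.5", diff)]:
    m1, lo1, hi1 = lp.bootstrap_mean_ci(pair.responses_1, n_boot=100, seed=0)
    m2, lo2, hi2 = lp.bootstrap_mean_ci(pair.responses_2, n_boot=100, seed=0)
    res = lp.permutation_test(pair, n_iter=1000, seed=5)
    print(f"{label}: S1 {m1:.2f} [{lo1:.2f}, {hi1:.2f}]  "
          f"S2 {m2:.2f} [{lo2:.2f}, {hi2:.2f}]  p = {res.p:.3f}")

sessions = [same.responses_1, same.responses_2, diff.responses_1, diff.responses_2]
across = lp.across_session_sd(sessions, seed=6)
within = lp.within_session_sd(sessions, seed=7)
print(f"across-session SD {across:.3f} vs within-session SD {within:.3f}")
# Equal-gain sessions are statistically indistinguishable (p >> 0.05); a
# 2.5x coupling-gain change is detected. When session means truly differ,
# across-session variability exceeds the within-session bootstrap SD.
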