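"""Behavioral state and pupil-LC coupling strength.

Sessions are simulated so that the coupling gain grows with the hit rate
of a Go/NoGo detection task. The per-session coupling slope is then
correlated with hit rate and with the SDT decision bias
c = -(z(H) + z(FA)) / 2.
"""
import numpy as np

import lcpupil as lp

hit_rates = np.linspace(0.45, 0.95, 9)
slopes, hits, biases = [], [], []
for i, h in enumerate(hit_rates):
    cfg = lp.SimConfig(duration=1500.0, gain=0.5 + 2.5 * float(h), seed=100 + i)
    train, trace, _ = lp.generate_session(cfg)
    fw = lp.forward_analysis(train, trace, roc_repeats=0)
    trials = lp.generate_behavior_session(float(h), 0.2, 150, seed=i)
    summary = lp.summarize_behavior(trials)
    slopes.append(fw.slope)
    hits.append(summary.hit_rate)
    biases.append(summary.bias)
    print(f"session {i}: hit {summary.hit_rate:.2f}  bias {summary.bias:+.2f}  "
          f"slope {fw.slope:.3f} z/spike")

cc_hit, p_hit = lp.correlate_slope_behavior(slopes, hits)
cc_bias, p_bias = lp.correlate_slope_behavior(slopes, biases)
print(f"slope vs hit rate:      c.c. = {cc_hit:+.2f} (p = {p_hit:.3g})")
print(f"slope vs decision bias: c.c. = {cc_bias:+.2f} (p = {p_bias:.3g})")
# Coupling strength tracks engagement: sessions with higher hit rate (and
# hence lower, more liberal bias) show steeper pupil-LC slopes, so the two
# correlations have opposite signs.
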