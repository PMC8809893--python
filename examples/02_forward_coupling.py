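"""Forward analysis: spike-cluster-triggered pupil responses.

Adjacent spikes are grouped into clusters using the unit's median ISI; the
peak z-scored pupil value in the 6 s after each cluster onset is collected
and summarised per cluster size. The linear slope (z-units per spike) is
the session's pupil-LC coupling strength.
"""
import lcpupil as lp

cfg = lp.SimConfig(duration=1800.0, seed=42)
train, trace, _ = lp.generate_session(cfg)

fw = lp.forward_analysis(train, trace)

print(f"median ISI threshold: {lp.median_isi(train):.2f} s")
print(f"clusters: {len(fw.clusters)}, triggered responses: {len(fw.responses)}")
print(fw.curve.as_frame().round(3).to_string(index=False))
print(f"slope = {fw.slope:.3f} +- {fw.slope_se:.3f} z/spike, "
      f"per-size-mean R^2 = {lp.fit_linear(fw.curve)[1]:.2f}")
# Mean peak grows roughly linearly with cluster size: each extra LC spike
# adds ~0.2 SD of pupil dilation under the default coupling gain, while
# large clusters (the strong responses) occur only a few percent of the time.
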