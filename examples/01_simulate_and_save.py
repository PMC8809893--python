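"""Generate one synthetic paired LC-pupil recording and save it as CSV.

The generator draws a bursty spike train (Poisson cluster onsets, geometric
cluster sizes), convolves each spike with a gamma-shaped pupil impulse
response peaking at 3 s, and adds slow Ornstein-Uhlenbeck drift plus
measurement noise. The ground-truth cluster sizes are known, so every
downstream analysis can be validated.
"""
from pathlib import Path

import lcpupil as lp
from lcpupil import io

out = Path("scratch/example_session")
out.mkdir(parents=True, exist_ok=True)

cfg = lp.SimConfig(duration=1200.0, seed=7)
train, trace, ground_truth = lp.generate_session(cfg)

io.write_spikes([train], out / "spikes.csv")
io.write_pupil(trace, out / "pupil.csv")

print(f"session: {cfg.duration:.0f} s at {cfg.rate_hz:.0f} Hz, gain {cfg.gain}")
print(f"spikes: {train.n_spikes} ({train.rate:.2f} Hz)")
print(f"ground-truth clusters: {len(ground_truth)}")
sizes = [c.size for c in ground_truth]
print(f"largest cluster: {max(sizes)} spikes; singleton fraction "
      f"{sizes.count(1) / len(sizes):.2f}")
print(f"wrote {out}/spikes.csv and {out}/pupil.csv")
# The singleton fraction ~0.55 reflects the geometric size law: occurrence
# decays monotonically with cluster size, so large bursts are rare.
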