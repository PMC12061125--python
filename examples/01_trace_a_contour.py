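"""Trace a single line pair and watch the binding front travel.

Builds a short two-line stimulus, seeds the left end of the upper line and
prints the modulation-onset latency at three probe positions.  Latency
grows with distance from the seed: the up-modulation spreads serially.
"""

import cortrace as ct
from cortrace import metrics

stim = ct.make_parallel_lines(length_px=120, distance_px=40, image_shape=(120, 180))
net = ct.build_network(ct.default_params(), stim.image.shape)
trace = ct.run(net, stim, n_steps=300)

onsets = metrics.onset_times(trace)
n = len(stim.target_path)
for name, q in (("P1", 0.25), ("P2", 0.5), ("P3", 0.75)):
    idx = int(q * (n - 1))
    print(f"{name} (path index {idx:3d}): onset at step {onsets.onsets[idx]:.0f}")
print(f"whole contour bound after {metrics.tracing_time(onsets):.0f} steps")
print("-> onset latency increases with path distance from the attentional seed")
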