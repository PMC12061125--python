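# cortrace

A deterministic, image-computable simulator of **incremental binding** in
mental curve tracing: how visual cortex, prompted by an attentional seed,
serially labels the elements of one contour among distractors by spreading
a firing-rate up-modulation along it.

When observers trace a curve mentally, the time they need grows with the
distance along the curve, and recordings in visual cortex show a matching
travelling wave of rate enhancement.  `cortrace` implements a mechanistic
account of this process: a V1–V2–V4 scale-space hierarchy of orientation
maps (rate-based two-compartment pyramidal-cell units coupled by Gabor
feedforward/feedback kernels) interacts reciprocally with a featureless
higher-order thalamic map that accumulates binding evidence from all areas,
thresholds it, and broadcasts a gating signal back.  Up-modulation requires
the *coincidence* of feedforward drive, apical feedback context and the
thalamic gate:

    τ_b v̇_b = −v_b g_leak + (β_b − v_b) k_ff g_FF (1 + λ g_B2 max(v_a, 0)) − κ v_b h_inh
    τ_a v̇_a = −v_a g_leak_a + (β_a − v_a) (g_FB⁺ + ξ g_FB⁻)
    τ v̇_HO  = −v_HO g_leak + (β_HO − v_HO) Σ_V k_HO,V g_HO,V

solved by steady-state iteration from a zero state.  Binding then spreads
from the seed as a front whose speed depends on the coarsest scale that
represents the target free of distractor interference (the "growth-cone"
property), and the package ships the measurement pipeline used to quantify
it — modulation indices, onset latencies, smoothed instantaneous speeds and
per-segment regression speeds — together with calculators for the
connectivity complexity of incremental-binding architectures.

The package is aimed at computational neuroscientists who want to probe the
thalamo-cortical account of attentional grouping: run lesion experiments,
generate the stimulus families (line pairs with varying separation,
crossings, rings, spirals, Pathfinder-style dashed fields), and measure how
tracing behaviour changes.

## Worked example

```python
import cortrace as ct
from cortrace import metrics

stim = ct.make_narrow_wide_pair(1/3)          # 40 px / 15 px separations
net = ct.build_network(ct.default_params(), stim.image.shape)
trace = ct.run(net, stim, n_steps=450)

onsets = metrics.onset_times(trace, labels=stim.segment_labels)
profile = metrics.speed_profile(onsets, segment_margin=8)
print({k: round(v, 2) for k, v in profile.segment_speeds.items()})
print("tracing time:", profile.tracing_time, "steps")
```

prints

```
{'wide1': 2.03, 'narrow': 1.7, 'wide2': 2.03}
tracing time: 128.0 steps
```

i.e. the attentional label moves at ≈2 V1 neurons per simulation step while
the distractor is 40 px away, and slows to ≈1.7 where the separation drops
to 15 px — tracing speed tracks target–distractor distance.  Removing the
V4→V2 feedback (`ct.lesion(net, ct.LesionSpec.parse(["FB:V4:V2"]))`)
flattens the profile to ≈1.5 everywhere: the dip is caused by the coarse
scale joining the spread only where it sees the target unambiguously.

The `examples/` directory contains one short script per capability
(tracing, growth-cone profile, lesions, crossings, complex shapes,
complexity counts).  A thin CLI wraps the same functions:
`cortrace scenario fig6_lesions`, `cortrace stimulus spiral --out s`,
`cortrace complexity`, `cortrace run --lesion FB:V4:V2 ...`.

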