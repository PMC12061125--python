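"""Gestalt disambiguation at a crossing.

Two contours cross at 90 degrees; the attentional seed selects which one is
bound.  Under the speed-calibrated default parameters the suppressive
feedback surround is shorter-range than the thalamic gate and the label
leaks onto both arms; a documented override (larger feedback envelope,
retuned suppression and gating) makes the label follow the seeded contour
through the junction and spare the other one (good continuation).
"""

import cortrace as ct
from cortrace import scenarios

CROSSING_OVERRIDE = {
    "sigma_fb": {"V2->V1": 2.4},
    "xi": {"V2->V1": -16.0},
    "lam": {"V1": 270.0},
    "rho_b2": {"V1": 5},
}

for label, params in (
    ("defaults", ct.default_params()),
    ("crossing-tuned", ct.default_params().override(CROSSING_OVERRIDE)),
):
    stim = ct.make_crossing(90.0)
    net = ct.build_network(params, stim.image.shape)
    trace = ct.run(net, stim, n_steps=300, seed_id="Att1")
    summary = scenarios.crossing_summary(trace, stim)
    print(
        f"{label:15s} attended contour bound: {summary['target_frac']:.0%}, "
        f"other contour bound: {summary['distractor_fracs'][0]:.0%}"
    )
print("-> with sufficient suppression reach the binding follows the smooth")
print("   continuation of the attended contour and ignores the crossing arm")
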