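# Model and methods

`cortrace` simulates mental curve tracing — *incremental binding* — as the
interplay of a hierarchical visual-cortex module (V1, V2, V4), a featureless
higher-order thalamic *interfacing* map (HO), and a task module that injects
an attentional seed.  This note records the model equations as implemented,
the parameter registry and how its defaults were chosen, what the synthetic
stimuli do and do not emulate, and the numerical decisions a user should
know about.

## Network

Areas are retinotopic maps at relative sizes 1, 0.5 and 0.25 of the input
(V1, V2, V4) and 0.66 (HO).  V1–V4 carry `n_theta = 12` orientation channels
on [0, π); HO carries a single binding-state channel.  Map shapes are
round-half-up of the input shape times the relative size.

A channel from area *Src* to area *Trgt* applies a space-feature separable
kernel to the source rates,

    g(x, y, θ) = f( resize( (Λ * r_Src)(x, y, θ), s_Trgt ) ),
    f(x) = min(max(x, 0), 1),

with zero padding in space, circular treatment on the orientation axis
(period π), linear-interpolation resizing to the target map
(align-corners-false convention) and a rectified, saturating nonlinearity.
Kernels are built at the **source** map's resolution, so a fixed kernel size
in neurons spans progressively larger input regions up the hierarchy — this
is what makes the scale space effective.

Kernel families (constructed in `cortrace.kernels`):

* **FF** — even-phase Gabor (aspect 1, wavelength λ = 2πσ) in space, Dirac
  on the orientation axis.  Positive and negative parts are separately
  normalised to sums of 1, removing the DC component.
* **Inh** — Gaussian in space, uniform over all orientations, composite
  normalised to sum 1; drives divisive inhibition.
* **FB** — the positive Gabor part paired with a rectified-cosine
  orientation kernel (angular difference doubled, so orthogonal
  orientations receive zero weight), plus the negative Gabor part paired
  with a uniform orientation kernel and scaled by ξ ≤ 0.  Collinear,
  like-oriented context excites the apical compartment; off-axis context of
  any orientation suppresses it.
* **B1** (cortex → HO) — uniform box over a ρ×ρ spatial neighbourhood and
  all orientations, sum 1 (a local space-feature average of the rates).
* **B2** (HO → cortex) — purely spatial uniform box, sum 0.5.

Connectivity: Inp→V1 (FF); V1→V2→V4 (FF); V2→V1 and V4→V2 (FB; V4 receives
none); self-Inh in each cortical area; V1/V2/V4→HO and S→HO (B1); HO→V1/V2/V4
(B2) — 15 channels in total.  The task module S is not simulated: it is a
constant square patch (default 2×2 HO pixels, amplitude 1) at the seed
location mapped into HO coordinates.

## Cell dynamics and the steady-state iteration

Pyramidal cells have a basal and an apical compartment:

    τ_b dv_b/dt = −v_b g_leak + (β_b − v_b) g_exc − κ v_b h_inh
    g_exc = k_ff · g_ff · (1 + λ · g_B2 · h_a),   h_a = max(v_a, 0)
    h_inh = 1.3 / (1 + exp(−(g_inh − 0.25)·20))
    τ_a dv_a/dt = −v_a g_leak_a + (β_a − v_a) g_fb

and thalamic cells accumulate binding evidence,

    τ dv_HO/dt = −v_HO g_leak + (β_HO − v_HO) Σ_V k_HO,V g_HO,V,
    r_HO = 1 / (1 + exp(−(2 v_HO − 1)·50)).

Rates are r = min(max(v_b, 0), 1).  The simulator iterates the **algebraic
fixed points** of these equations in fully synchronous (Jacobi) sweeps from
a zero state: all conductances of a sweep are computed from the previous
sweep's rates, then apical, thalamic and basal potentials are updated.  One
sweep is the unit of time for all latencies and speeds ("neurons/step").  A
run stops after `n_steps` (default 600) or as soon as one further sweep
changes every field by less than `tol` (default 1e-6).  A test cross-checks
the fixed-point iteration against dense forward-Euler integration of the
differential equations on a 16×16 network (equilibria agree to 1e-4).

Two numerical guards: (i) when the suppressive feedback drives
`g_fb ≤ −g_leak_a` the apical ODE has no stable fixed point; the compartment
is then assigned a negative potential (rectified to `h_a = 0`), which is the
limit behaviour.  (ii) conductances are held fixed within a sweep; the
apical update feeds the same-sweep basal update through `h_a`.

## How binding propagates

Feedforward drive alone produces the *base representation* (V1 rates ≈ 0.3
on a contour).  The B1 channels average the rates over local space-feature
neighbourhoods; on the base representation this evidence stays below the HO
sigmoid's threshold (v_HO ≈ 0.40–0.45 < 0.5).  The seed pushes its HO
neighbourhood over threshold; the B2 gate opens around it; cortical cells
inside the gate whose apical compartment carries compatible feedback context
are up-modulated (rates → ≈ 1); their elevated evidence pushes the
neighbouring HO positions over threshold, and the bound region grows — a
travelling front whose speed is set by the gate and evidence footprints and
by the margin between base evidence and threshold.

The growth-cone behaviour (faster tracing where the distractor is far)
emerges because the V2 loop joins only where V2's apical context survives:
at the V4 scale the 15-px-separated distractor falls on the negative flank
of the V4→V2 feedback Gabor (the uniform orientation kernel includes the
parallel distractor), shutting V2's apical compartment along the narrow
section, while the 40-px separation lies outside the kernel.  V1's apical
context (from V2, whose kernels are too small to see the distractor at
either distance) is available along the whole contour.

## Parameter registry

All scalar constants live in `cortrace.config.ModelParams`.  Spatial scales
are in pixels of the map the kernel lives on; gains and potentials are
dimensionless.  The published parameter table for the reference model is not
available, so the shipped defaults were fixed by the calibration procedure
the package exposes (`cortrace.scenarios.calibrate`): a search over the
gains (`k_ff`, `k_ho`, `λ`), the feedback scales (`σ_fb`, `ξ`) and the
binding footprints (`ρ_b1`, `ρ_b2`) minimising the squared error to the
reference intact-condition segment speeds (2.14, 1.63, 2.12 neurons/step)
under two hard constraints: the no-seed network must remain silent
(max v_HO safely below threshold everywhere, including the taper corners of
the distractor), and the V1-only loop (all B1 channels from V2/V4 removed)
must still trace.  Lesion experiments reuse the calibrated defaults
unchanged.

Key defaults and what they do:

| parameter | default | role |
| --- | --- | --- |
| `k_ff` | V1 0.33, V2 1.3, V4 3.0 | feedforward gains; V1 low → high attended/base contrast, V4 high → saturated (small attended/base ratio, keeps narrow-segment interference intact during tracing) |
| `k_ho` | V1 9.2, V2 8.0, V4 1.0, S 6.0 | evidence gains; set the base-to-threshold margin and each scale's share of the front |
| `lam` | V1 160, V2 100, V4 0 | gating gain of the three-way coincidence term (V4 has no apical compartment) |
| `xi` | V2→V1 −8, V4→V2 −40 | suppressive feedback scale; the uniform orientation kernel averages over all 12 channels, hence the large magnitudes |
| `sigma_fb` | V2→V1 1.2, V4→V2 1.3 | feedback Gabor scale (source pixels); 1.3 at V4 puts the negative flank at ≈15 input px |
| `rho_b1` / `rho_b2` | 5/11/5 and 7/7/3 | evidence and gate footprints per area |
| `beta_b, beta_a` | 1.3 | reversal potentials (rates clip at 1) |
| `kappa_b` | V1 0.3, V2 1.0, V4 0.3 | divisive-inhibition scale (biased competition) |

With these defaults the narrow-wide experiment yields segment speeds
(2.03, 1.70, 2.03) intact, (1.52, 1.50, 1.53) with V4→V2 feedback removed,
(1.49, 1.25, 1.51) with V2/V4→HO removed, and (1.19, 1.20, 1.20) with both
lesions — the full qualitative pattern (flat profiles for the feedback and
combined lesions, a preserved dip for the interfacing-module lesion,
compound slowing) at quantitative deviations of at most ≈0.11 neurons/step
from the reference values.

## Stimuli

Generators return a luminance image in [0, 1] plus annotations (seed
locations, ordered target path, per-position segment labels, distractor
paths) used only by the evaluation code.  Contours are anti-aliased strokes
of width 2 px; coordinates are 0-based (row, col).  All generators are
bit-exact reproducible; the Pathfinder-style generator routes all
randomness through an explicit seed.

The narrow-wide pair uses linear tapers of 50 px between the 40-px and
15-px separations.  A much shorter taper makes the distractor jog nearly
vertical; the resulting multi-orientation corner energy is strong enough to
ignite the thalamic map without any seed, which is a property of the corner
stimulus, not of the tracing manipulation the experiment probes.  Segment
labels cut at the taper midpoints; per-segment regressions drop 8 positions
at each segment boundary to avoid taper and contour-end transients.

What the synthetic stimuli do **not** emulate: luminance noise, contrast
variation, eccentricity-dependent scaling, curvature statistics of natural
contours, and the exact statistics of the published Pathfinder dataset
(the generator reproduces the style — curvature-bounded dashed random
walks with a seed dot — not the dataset).  Passing tests therefore show
that the mechanism behaves correctly on clean laboratory-style displays,
not that it is robust to natural images.

## Metrics

* **Modulation index**: MI = 2(r_att − r_base)/(r_att + r_base) per
  (position, orientation) neuron; positions with zero activity in both
  epochs are excluded.  The baseline epoch defaults to the step before the
  first onset along the path (base representation formed, gate still
  closed).
* **Onset time**: activity is summed over orientations per path position;
  the onset is the first step at which it crosses 50% of its maximum over
  the trial.
* **Speeds**: onsets are smoothed with the binomial kernel [1,4,6,4,1]/16
  (odd-reflection padding at the contour ends, which leaves affine onset
  profiles exactly unchanged); pairwise speeds are inverse smoothed-onset
  differences, masked with a warning where non-increasing; per-segment
  speeds are inverse OLS slopes of the raw onsets against path index.  For
  curved geometries pairwise speeds are multiplied by the arc length
  between probes (px/step).

## Known limitations

* **Crossing disambiguation is parameter-regime-dependent.**  Under the
  shipped (speed-calibrated) defaults, seeding one arm of a 90° crossing
  up-modulates both arms: the orientation-unspecific suppression that
  should veto the orthogonal arm (V2→V1 negative feedback) is shorter-range
  than the featureless thalamic gate, so the binding signal tunnels across
  the junction.  In this kernel family (aspect-1 Gabors with λ = 2πσ) the
  suppression reach and the negative-flank radius are tied to the same σ:
  every σ_fb(V2→V1) large enough to out-reach the gate (≥ 2.4 V2 px) puts
  the renormalised negative flank onto the 15-px distractor of the
  narrow-wide stimulus and destroys the flat lesion profiles.  The override
  `{"sigma_fb": {"V2->V1": 2.4}, "xi": {"V2->V1": -16}, "lam": {"V1": 270},
  "rho_b2": {"V1": 5}}` produces clean Gestalt behaviour (100% of the
  attended contour bound, 0% of the other) at the cost of a narrow-segment
  dip in the lesioned profiles; `examples/04_crossing.py` demonstrates it.
* Tracing speed on rings is roughly curvature-independent in the presence
  of distractors; a curvature-dependent slowdown appears only for the
  smallest radii.
* Units are abstract: one sweep is the time unit, one V1 pixel the space
  unit; no mapping to milliseconds or degrees of visual angle is attempted.
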