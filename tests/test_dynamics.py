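import numpy as np
import pytest

import cortrace as ct
from cortrace import dynamics as dyn
from cortrace.model import LesionSpec, build_network, clip01, lesion
from cortrace.stimuli import Stimulus


def test_printed_nonlinearities():
    # inhibitory interneuron response at its midpoint
    assert dyn.f_inh(0.25) == pytest.approx(1.3 / 2)
    # thalamic sigmoid: midpoint and steep segregation of binding states
    assert dyn.f_ho(0.5) == pytest.approx(0.5)
    assert dyn.f_ho(0.6) - dyn.f_ho(0.4) > 0.98


def test_basal_fixed_point_requires_feedforward_drive():
    p = ct.default_params()
    shape = (p.n_theta, 4, 4)
    g = {
        "ff": {v: np.zeros(shape) for v in dyn.CORTICAL},
        "inh": {v: np.zeros(shape) for v in dyn.CORTICAL},
        "b2": {v: np.full(shape[1:], 0.5) for v in dyn.CORTICAL},
    }
    h_a = {v: np.full(shape, 0.9) for v in dyn.CORTICAL}
    v_b = dyn.basal_update(g, h_a, p)
    for v in dyn.CORTICAL:
        assert np.allclose(v_b[v], 0.0)  # gating and context alone cannot drive


def test_basal_fixed_point_without_gate_is_pure_feedforward():
    p = ct.default_params()
    shape = (p.n_theta, 4, 4)
    g = {
        "ff": {v: np.full(shape, 0.6) for v in dyn.CORTICAL},
        "inh": {v: np.zeros(shape) for v in dyn.CORTICAL},
        "b2": {v: np.zeros(shape[1:]) for v in dyn.CORTICAL},
    }
    strong = {v: np.full(shape, 0.9) for v in dyn.CORTICAL}
    none = {v: np.zeros(shape) for v in dyn.CORTICAL}
    assert np.allclose(
        dyn.basal_update(g, strong, p)["V1"], dyn.basal_update(g, none, p)["V1"]
    )


def test_apical_fixed_point_limits():
    p = ct.default_params()
    net = build_network(p, (16, 16))
    g = {"fb": {"V1": np.full((p.n_theta, 16, 16), 1e6), "V2": 0.0}}
    v_a = dyn.apical_update(g, net, p)
    assert np.allclose(v_a["V1"], p.beta_a, rtol=1e-4)  # saturation at beta_a
    assert np.allclose(v_a["V2"], 0.0)  # no feedback, no apical potential
    assert np.allclose(v_a["V4"], 0.0)  # V4 never receives feedback


def test_strongly_suppressive_feedback_shuts_the_apical_compartment():
    p = ct.default_params()
    net = build_network(p, (8, 8))
    g = {"fb": {"V1": np.full((p.n_theta, 8, 8), -5.0), "V2": 0.0}}
    v_a = dyn.apical_update(g, net, p)
    assert np.all(np.maximum(v_a["V1"], 0.0) == 0.0)
    assert np.all(np.isfinite(v_a["V1"]))


def test_blank_image_stays_at_zero_fixed_point():
    blank = Stimulus(
        image=np.zeros((48, 48)), seeds=[], target_path=[(24, 24)], segment_labels=["x"]
    )
    net = build_network(ct.default_params(), blank.image.shape)
    trace = ct.run(net, blank, n_steps=10, record_every=0)
    state = trace.final_state
    for v in dyn.CORTICAL:
        assert np.all(state.v_b[v] == 0.0) and np.all(state.v_a[v] == 0.0)
    assert np.all(state.v_ho == 0.0)


def test_state_is_bounded_by_reversal_potentials(tiny_trace):
    p = ct.default_params()
    state = tiny_trace.final_state
    for v in dyn.CORTICAL:
        assert state.v_b[v].min() >= 0.0 and state.v_b[v].max() <= p.beta_b + 1e-9
        assert state.v_a[v].max() <= p.beta_a + 1e-9
    assert state.v_ho.min() >= 0.0 and state.v_ho.max() <= p.beta_ho + 1e-9


def test_tiny_line_is_traced_to_the_end(tiny_trace):
    from cortrace import metrics

    onsets = metrics.onset_times(tiny_trace)
    assert np.all(np.isfinite(onsets.onsets))
    assert onsets.onsets[-1] > onsets.onsets[0]


def test_converged_state_is_a_fixed_point(tiny_line_stimulus, tiny_trace):
    """One further synchronous sweep changes every field by < tolerance."""
    assert tiny_trace.meta["converged_at"] is not None
    net = build_network(ct.default_params(), tiny_line_stimulus.image.shape)
    state = tiny_trace.final_state
    p = net.params
    rates = state.rates()
    task = dyn.make_task_input(net, tiny_line_stimulus.seeds[0][1], p)
    inp = clip01(tiny_line_stimulus.image)
    rates["Inp"] = inp
    g = dyn.compute_conductances(net, rates, task)
    v_a = dyn.apical_update(g, net, p)
    h_a = {v: np.maximum(v_a[v], 0.0) for v in dyn.CORTICAL}
    v_ho = dyn.ho_update(g, p)
    v_b = dyn.basal_update(g, h_a, p)
    delta = max(
        max(np.max(np.abs(v_b[v] - state.v_b[v])) for v in dyn.CORTICAL),
        float(np.max(np.abs(v_ho - state.v_ho))),
    )
    assert delta < 1e-5


def test_no_seed_and_gating_lesion_leave_base_representation(tiny_line_stimulus):
    """Binding requires both the attentional seed and the thalamic gate."""
    net = build_network(ct.default_params(), tiny_line_stimulus.image.shape)
    seeded = ct.run(net, tiny_line_stimulus, n_steps=120, record_every=0)
    unseeded = ct.run(net, tiny_line_stimulus, n_steps=120, record_every=0, with_seed=False)
    gateless = ct.run(
        lesion(net, LesionSpec.parse(["B2:HO:V1", "B2:HO:V2", "B2:HO:V4"])),
        tiny_line_stimulus,
        n_steps=120,
        record_every=0,
    )
    base_peak = unseeded.path_rates_sum.max()
    assert seeded.path_rates_sum.max() > 2 * base_peak  # seeding up-modulates
    assert gateless.path_rates_sum.max() < 1.1 * base_peak
    assert np.allclose(gateless.path_rates_sum[-1], unseeded.path_rates_sum[-1], atol=1e-6)


def euler_integrate(net, stimulus, params, t_end=200.0, dt=0.02):
    """Forward-Euler oracle for the conductance ODEs, dense in time."""
    state = dyn.ModelState.zeros(net)
    task = dyn.make_task_input(net, stimulus.seeds[0][1], params)
    inp = clip01(np.asarray(stimulus.image, dtype=float))
    n = int(round(t_end / dt))
    for _ in range(n):
        rates = state.rates()
        rates["Inp"] = inp
        g = dyn.compute_conductances(net, rates, task)
        new_b, new_a = {}, {}
        for v in dyn.CORTICAL:
            h_inh = dyn.f_inh(g["inh"][v])
            h_a = np.maximum(state.v_a[v], 0.0)
            g_exc = params.k_ff[v] * g["ff"][v] * (
                1.0 + params.lam[v] * g["b2"][v] * h_a
            )
            dv_b = (
                -state.v_b[v] * params.g_leak_b
                + (params.beta_b - state.v_b[v]) * g_exc
                - params.kappa_b[v] * state.v_b[v] * h_inh
            ) / params.tau_b
            g_fb = g["fb"].get(v, 0.0)
            dv_a = (
                -state.v_a[v] * params.g_leak_a
                + (params.beta_a - state.v_a[v]) * g_fb
            ) / params.tau_a
            new_b[v] = state.v_b[v] + dt * dv_b
            new_a[v] = state.v_a[v] + dt * np.asarray(dv_a)
        g_exc_ho = sum(params.k_ho[s] * np.asarray(gv) for s, gv in g["ho"].items())
        dv_ho = (
            -state.v_ho * params.g_leak_ho + (params.beta_ho - state.v_ho) * g_exc_ho
        ) / params.tau_ho
        state = dyn.ModelState(
            v_b=new_b, v_a=new_a, v_ho=state.v_ho + dt * dv_ho, step=state.step + 1
        )
    return state


def test_fixed_point_sweeps_match_euler_integration_at_equilibrium():
    """The steady-state iteration and a dense forward-Euler integration of
    the conductance ODEs settle on the same equilibrium (16x16, 2
    orientation channels)."""
    params = ct.default_params().override(
        {"n_theta": 2, "xi": {"V2->V1": -0.5, "V4->V2": -0.5}}
    )
    image = np.zeros((16, 16))
    image[8, 2:14] = 1.0
    stim = Stimulus(
        image=image,
        seeds=[("Att", (8, 2))],
        target_path=[(8, c) for c in range(2, 14)],
        segment_labels=["line"] * 12,
    )
    net = build_network(params, stim.image.shape)
    fixed = ct.run(net, stim, params=params, n_steps=200, record_every=0).final_state
    euler = euler_integrate(net, stim, params)
    for v in dyn.CORTICAL:
        assert np.max(np.abs(fixed.v_b[v] - euler.v_b[v])) < 1e-4
        assert np.max(np.abs(np.maximum(fixed.v_a[v], 0) - np.maximum(euler.v_a[v], 0))) < 1e-4
    assert np.max(np.abs(fixed.v_ho - euler.v_ho)) < 1e-4


def test_run_validates_step_count(tiny_line_stimulus):
    net = build_network(ct.default_params(), tiny_line_stimulus.image.shape)
    with pytest.raises(ValueError):
        ct.run(net, tiny_line_stimulus, n_steps=0)
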