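"""Cell dynamics and the simulation loop.

Pyramidal cells have two compartments.  The basal potential integrates
feedforward drive, divisive surround inhibition and the gain-modulating
coincidence of feedback context (apical) with the thalamic gating signal:

    tau_b dv_b/dt = -v_b g_leak + (beta_b - v_b) g_exc - kappa v_b h_inh,
    g_exc = k_ff g_ff (1 + lambda g_b2 h_a),    h_a = max(v_a, 0),

the apical potential integrates feedback alone,

    tau_a dv_a/dt = -v_a g_leak_a + (beta_a - v_a) g_fb,

and higher-order thalamic cells accumulate binding evidence from all cortical
areas plus the task module,

    tau_ho dv_ho/dt = -v_ho g_leak_ho + (beta_ho - v_ho) sum_V k_ho_V g_ho_V.

The simulator iterates the algebraic fixed points of these equations in
fully synchronous (Jacobi) sweeps from a zero initial state: all channel
conductances of a sweep are computed from the previous sweep's rates, then
apical, thalamic and basal potentials are updated.  One sweep is the unit of
time for every latency and speed metric ("neurons/step").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ModelParams
from .model import Network, apply_channel, apply_fb_channel, clip01
from .stimuli import Stimulus

__all__ = [
    "ModelState",
    "TraceRecord",
    "f_inh",
    "f_ho",
    "compute_conductances",
    "basal_update",
    "apical_update",
    "ho_update",
    "make_task_input",
    "run",
]

CORTICAL = ("V1", "V2", "V4")


def f_inh(x: np.ndarray) -> np.ndarray:
    """Response of the local inhibitory interneuron pool."""
    return 1.3 / (1.0 + np.exp(-(x - 0.25) * 20.0))


def f_ho(x: np.ndarray) -> np.ndarray:
    """Steep sigmoid separating non-binding from binding states."""
    return 1.0 / (1.0 + np.exp(-(2.0 * x - 1.0) * 50.0))


@dataclass
class ModelState:
    """Basal/apical potentials per cortical area plus the thalamic field."""

    v_b: dict  # area -> (n_theta, h, w)
    v_a: dict  # area -> (n_theta, h, w); identically 0 for V4
    v_ho: np.ndarray  # (h, w)
    step: int = 0

    @classmethod
    def zeros(cls, network: Network) -> "ModelState":
        n_theta = network.params.n_theta
        v_b = {
            v: np.zeros((n_theta, *network.areas[v].shape), dtype=float)
            for v in CORTICAL
        }
        v_a = {
            v: np.zeros((n_theta, *network.areas[v].shape), dtype=float)
            for v in CORTICAL
        }
        return cls(v_b=v_b, v_a=v_a, v_ho=np.zeros(network.areas["HO"].shape), step=0)

    def rates(self) -> dict:
        out = {v: clip01(self.v_b[v]) for v in CORTICAL}
        out["HO"] = f_ho(self.v_ho)
        return out


@dataclass
class TraceRecord:
    """Per-step recordings of a run.

    ``path_rates`` holds the per-orientation V1 rates at every target-path
    position for every step, shape ``(n_steps, n_path, n_theta)``;
    ``distractor_rates`` the theta-summed V1 rates along each annotated
    distractor path.  ``snapshots`` holds sparse theta-summed rate maps.
    """

    steps: list = field(default_factory=list)
    path_rates: np.ndarray | None = None  # (T, n_path, n_theta)
    distractor_rates: list = field(default_factory=list)  # [(T, n_path_i)]
    ho_path: np.ndarray | None = None  # (T, n_path) HO rates mapped to the path
    snapshots: dict = field(default_factory=dict)  # step -> {area: 2D map}
    meta: dict = field(default_factory=dict)
    final_state: ModelState | None = None

    @property
    def path_rates_sum(self) -> np.ndarray:
        """Theta-summed V1 rate series along the target path, (T, n_path)."""
        return self.path_rates.sum(axis=2)


def make_task_input(
    network: Network, seed_pos: tuple[int, int], params: ModelParams
) -> np.ndarray:
    """Constant external input map into the interfacing module.

    The task module is not simulated; it contributes a fixed square patch of
    amplitude ``seed_amplitude`` at the seed location mapped into HO
    coordinates.
    """
    ho_shape = network.areas["HO"].shape
    in_shape = network.input_shape
    task = np.zeros(ho_shape)
    r = int(np.floor((seed_pos[0] + 0.5) * ho_shape[0] / in_shape[0]))
    c = int(np.floor((seed_pos[1] + 0.5) * ho_shape[1] / in_shape[1]))
    half = params.seed_footprint // 2
    r0, r1 = max(r - half, 0), min(r - half + params.seed_footprint, ho_shape[0])
    c0, c1 = max(c - half, 0), min(c - half + params.seed_footprint, ho_shape[1])
    task[r0:r1, c0:c1] = params.seed_amplitude
    return task


def compute_conductances(
    network: Network,
    rates: dict,
    task_input: np.ndarray | None,
    g_ff_inp: np.ndarray | None = None,
) -> dict:
    """Assemble every channel conductance from a set of source rates.

    ``rates`` maps area name to its rate field (cortical areas: per-theta
    stacks, HO: 2D).  ``g_ff_inp`` optionally supplies the precomputed
    (stimulus-constant) Inp->V1 feedforward conductance.  Disabled channels
    contribute identically zero.  Returns a dict with per-area entries
    ``ff``, ``inh``, ``fb``, ``b2`` and per-source HO entries ``ho``.
    """
    p = network.params
    g = {
        "ff": {},
        "inh": {},
        "fb": {},
        "b2": {},
        "ho": {},
    }
    for ch in network.channels:
        tgt_shape = network.areas[ch.target].shape if ch.target != "S" else None
        if ch.channel_type == "FF":
            if not ch.enabled:
                g["ff"][ch.target] = 0.0
            elif ch.source == "Inp":
                g["ff"][ch.target] = (
                    g_ff_inp
                    if g_ff_inp is not None
                    else apply_channel(ch.kernel, rates["Inp"], tgt_shape)
                )
            else:
                g["ff"][ch.target] = apply_channel(ch.kernel, rates[ch.source], tgt_shape)
        elif ch.channel_type == "Inh":
            g["inh"][ch.target] = (
                apply_channel(ch.kernel, rates[ch.source], tgt_shape)
                if ch.enabled
                else 0.0
            )
        elif ch.channel_type == "FB":
            g["fb"][ch.target] = (
                apply_fb_channel(
                    ch.kernel,
                    ch.kernel_neg,
                    p.xi[f"{ch.source}->{ch.target}"],
                    rates[ch.source],
                    tgt_shape,
                )
                if ch.enabled
                else 0.0
            )
        elif ch.channel_type == "B2":
            g["b2"][ch.target] = (
                apply_channel(ch.kernel, rates["HO"], tgt_shape) if ch.enabled else 0.0
            )
        elif ch.channel_type == "B1":
            if ch.source == "S":
                g["ho"]["S"] = (
                    clip01(task_input)
                    if (ch.enabled and task_input is not None)
                    else 0.0
                )
            else:
                g["ho"][ch.source] = (
                    apply_channel(ch.kernel, rates[ch.source], tgt_shape)
                    if ch.enabled
                    else 0.0
                )
    return g


def basal_update(g: dict, h_a: dict, params: ModelParams) -> dict:
    """Fixed point of the basal equation for every cortical area.

    Feedback enters only through the multiplicative gating term; without
    feedforward drive the potential is zero regardless of apical or gating
    input.
    """
    out = {}
    for v in CORTICAL:
        h_inh = f_inh(g["inh"][v])
        gate = g["b2"][v]
        g_exc = params.k_ff[v] * g["ff"][v] * (1.0 + params.lam[v] * gate * h_a[v])
        out[v] = params.beta_b * g_exc / (
            params.g_leak_b + g_exc + params.kappa_b[v] * h_inh
        )
    return out


def apical_update(g: dict, network: Network, params: ModelParams) -> dict:
    """Fixed point of the apical equation; V4 receives no feedback."""
    out = {}
    for v in CORTICAL:
        g_fb = g["fb"].get(v, 0.0)
        if np.isscalar(g_fb) and g_fb == 0.0:
            out[v] = network_zero(network, v)
        else:
            # strongly suppressive feedback (g_fb <= -g_leak_a) leaves the
            # ODE without a stable fixed point; the compartment is then fully
            # shut off (any negative value rectifies to h_a = 0)
            den = params.g_leak_a + g_fb
            out[v] = np.where(
                den > 0.05 * params.g_leak_a,
                params.beta_a * g_fb / np.maximum(den, 1e-12),
                -params.beta_a,
            )
    return out


def network_zero(network: Network, area: str) -> np.ndarray:
    return np.zeros((network.params.n_theta, *network.areas[area].shape))


def ho_update(g: dict, params: ModelParams) -> np.ndarray:
    """Fixed point of the thalamic evidence-accumulation equation."""
    g_exc = 0.0
    for src, gv in g["ho"].items():
        g_exc = g_exc + params.k_ho[src] * gv
    return params.beta_ho * g_exc / (params.g_leak_ho + g_exc)


def _path_index_arrays(path: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(path)
    return arr[:, 0], arr[:, 1]


def run(
    network: Network,
    stimulus: Stimulus,
    params: ModelParams | None = None,
    n_steps: int = 600,
    record_every: int = 50,
    seed_id: str | None = None,
    with_seed: bool = True,
    tol: float = 1e-6,
) -> TraceRecord:
    """Simulate the network on a stimulus from a zero initial state.

    Each step is one synchronous sweep: conductances from the previous
    rates, then apical, thalamic and basal fixed-point updates.  The run
    stops early once one further sweep changes every state field by less
    than ``tol`` (the stable equilibrium).  Raises ``FloatingPointError`` on
    the first non-finite state field.
    """
    if params is None:
        params = network.params
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    state = ModelState.zeros(network)

    task = None
    if with_seed and stimulus.seeds:
        seeds = dict((sid, pos) for sid, pos in stimulus.seeds)
        sid = seed_id if seed_id is not None else stimulus.seeds[0][0]
        task = make_task_input(network, seeds[sid], params)

    # the input is constant, so its feedforward drive is computed once
    inp_rates = clip01(np.asarray(stimulus.image, dtype=float))
    ff_ch = network.channel("FF", "Inp", "V1")
    g_ff_inp = (
        apply_channel(ff_ch.kernel, inp_rates, network.areas["V1"].shape)
        if ff_ch.enabled
        else 0.0
    )

    n_theta = params.n_theta
    path_rows, path_cols = _path_index_arrays(stimulus.target_path)
    dis_idx = [_path_index_arrays(pth) for pth in stimulus.distractor_paths]
    ho_shape = network.areas["HO"].shape
    ho_rows = np.floor((path_rows + 0.5) * ho_shape[0] / network.input_shape[0]).astype(int)
    ho_cols = np.floor((path_cols + 0.5) * ho_shape[1] / network.input_shape[1]).astype(int)

    path_rates = np.zeros((n_steps, len(path_rows), n_theta))
    dis_rates = [np.zeros((n_steps, len(r))) for r, _ in dis_idx]
    ho_path = np.zeros((n_steps, len(path_rows)))
    record = TraceRecord(
        meta={
            "n_steps": n_steps,
            "record_every": record_every,
            "tol": tol,
            "with_seed": with_seed and task is not None,
            "params_digest": params.digest(),
            "stimulus_meta": dict(stimulus.meta),
            "target_path": [list(p) for p in stimulus.target_path],
        }
    )

    converged_at = None
    t = 0
    for t in range(n_steps):
        rates = state.rates()
        g = compute_conductances(network, rates, task, g_ff_inp=g_ff_inp)
        v_a = apical_update(g, network, params)
        h_a = {v: np.maximum(v_a[v], 0.0) for v in CORTICAL}
        v_ho = ho_update(g, params)
        v_b = basal_update(g, h_a, params)

        delta = max(
            max(np.max(np.abs(v_b[v] - state.v_b[v])) for v in CORTICAL),
            max(np.max(np.abs(v_a[v] - state.v_a[v])) for v in CORTICAL),
            float(np.max(np.abs(v_ho - state.v_ho))),
        )
        state = ModelState(v_b=v_b, v_a=v_a, v_ho=np.asarray(v_ho, dtype=float), step=t + 1)
        for area, fld in state.v_b.items():
            if not np.all(np.isfinite(fld)):
                raise FloatingPointError(f"non-finite basal potential in {area} at step {t}")
        if not np.all(np.isfinite(state.v_ho)):
            raise FloatingPointError(f"non-finite thalamic potential at step {t}")

        r_v1 = clip01(state.v_b["V1"])
        path_rates[t] = r_v1[:, path_rows, path_cols].T
        for k, (rr, cc) in enumerate(dis_idx):
            dis_rates[k][t] = r_v1[:, rr, cc].sum(axis=0)
        ho_path[t] = f_ho(state.v_ho)[ho_rows, ho_cols]
        record.steps.append(t)

        if record_every and (t % record_every == 0 or t == n_steps - 1):
            record.snapshots[t] = {
                v: clip01(state.v_b[v]).sum(axis=0) for v in CORTICAL
            } | {"HO": f_ho(state.v_ho).copy()}

        if delta < tol and t > 0:
            converged_at = t
            break

    n_done = t + 1
    record.path_rates = path_rates[:n_done]
    record.distractor_rates = [d[:n_done] for d in dis_rates]
    record.ho_path = ho_path[:n_done]
    record.meta["converged_at"] = converged_at
    record.meta["steps_run"] = n_done
    record.final_state = state
    return record
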