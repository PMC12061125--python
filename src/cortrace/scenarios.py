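"""Experiment orchestration: presets replicating the curve-tracing
experiments, lesion batteries, sweeps, calibration, and output bundles.

Every scenario builds its stimuli with the generators in
:mod:`cortrace.stimuli`, runs the simulator and writes a bundle: an HDF5
trace file, CSV tables (onsets, speeds), PNG panels and a JSON summary
carrying the full configuration hash for provenance.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import metrics, stimuli
from .config import ExperimentConfig, ModelParams, default_params
from .dynamics import TraceRecord, run
from .model import LesionSpec, build_network, lesion

logger = logging.getLogger("cortrace")

__all__ = [
    "SCENARIOS",
    "LESION_SETS",
    "run_experiment",
    "segment_speeds",
    "run_scenario",
    "calibrate",
]

# the lesion battery of the ablation experiments
LESION_SETS = {
    "intact": [],
    "fb_v4_v2": ["FB:V4:V2"],
    "b1_v2v4_ho": ["B1:V2:HO", "B1:V4:HO"],
    "combined": ["FB:V4:V2", "B1:V2:HO", "B1:V4:HO"],
}

# printed reference speeds (neurons/step) for the narrow-wide experiment
REFERENCE_SPEEDS = {
    "intact": (2.14, 1.63, 2.12),
    "fb_v4_v2": (1.50, 1.49, 1.51),
    "b1_v2v4_ho": (1.50, 1.36, 1.52),
    "combined": (1.14, 1.11, 1.10),
}

# positions dropped at each segment boundary in the per-segment regressions,
# guarding against contour-end and taper transients
SEGMENT_MARGIN = 8


def _make_stimulus(spec: dict) -> stimuli.Stimulus:
    spec = dict(spec)
    name = spec.pop("generator")
    factory = getattr(stimuli, f"make_{name}", None)
    if factory is None:
        raise ValueError(f"unknown stimulus generator {name!r}")
    return factory(**spec)


def run_experiment(
    config: ExperimentConfig,
    stimulus: stimuli.Stimulus | None = None,
    with_seed: bool = True,
) -> TraceRecord:
    """Run one simulation described by an :class:`ExperimentConfig`."""
    if stimulus is None:
        stimulus = _make_stimulus(config.stimulus)
    params = config.resolved_params()
    net = build_network(params, stimulus.image.shape)
    if config.lesions:
        net = lesion(net, LesionSpec.parse(list(config.lesions)))
    trace = run(
        net,
        stimulus,
        n_steps=config.n_steps,
        record_every=config.record_every,
        seed_id=config.seed_id,
        with_seed=with_seed,
    )
    trace.meta["config_digest"] = config.digest()
    trace.meta["lesions"] = list(config.lesions)
    return trace


def segment_speeds(
    trace: TraceRecord, stimulus: stimuli.Stimulus, segment_margin: int = SEGMENT_MARGIN
) -> dict:
    """Per-segment regression speeds (neurons/step) of a recorded run."""
    onsets = metrics.onset_times(trace, labels=stimulus.segment_labels)
    profile = metrics.speed_profile(onsets, segment_margin=segment_margin)
    return profile.segment_speeds


def narrow_wide_battery(
    conditions=None,
    params: ModelParams | None = None,
    stimulus: stimuli.Stimulus | None = None,
    n_steps: int = 450,
) -> dict:
    """Run the narrow-wide stimulus intact and under the lesion battery.

    Returns ``{condition: {"segment_speeds": {...}, "trace": TraceRecord}}``
    with per-segment regression speeds in neurons/step.
    """
    params = params or default_params()
    stimulus = stimulus or stimuli.make_narrow_wide_pair(1 / 3)
    net0 = build_network(params, stimulus.image.shape)
    out = {}
    for cond in conditions or LESION_SETS:
        spec = LESION_SETS[cond]
        net = lesion(net0, LesionSpec.parse(spec)) if spec else net0
        trace = run(net, stimulus, n_steps=n_steps, record_every=0)
        out[cond] = {
            "segment_speeds": segment_speeds(trace, stimulus),
            "trace": trace,
        }
        logger.info("battery %s: %s", cond, out[cond]["segment_speeds"])
    return out


# ---------------------------------------------------------------------------
# output bundle helpers


def _write_bundle(
    outdir: Path,
    name: str,
    config: ExperimentConfig,
    stimulus: stimuli.Stimulus,
    trace: TraceRecord,
    summary: dict,
) -> None:
    import csv

    import h5py

    outdir.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    with h5py.File(outdir / f"{name}_trace.h5", "w") as f:
        f.attrs["config_digest"] = digest
        f.attrs["steps_run"] = trace.meta["steps_run"]
        f.create_dataset("path_rates", data=trace.path_rates, compression="gzip")
        f.create_dataset("ho_path", data=trace.ho_path, compression="gzip")
        for step, maps in trace.snapshots.items():
            grp = f.create_group(f"snapshots/{step:05d}")
            for area, field in maps.items():
                grp.create_dataset(area, data=field, compression="gzip")

    onsets = metrics.onset_times(trace, labels=stimulus.segment_labels)
    with open(outdir / f"{name}_onsets.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["path_index", "row", "col", "label", "onset_step"])
        for i, ((r, c), lab) in enumerate(zip(stimulus.target_path, stimulus.segment_labels)):
            w.writerow([i, r, c, lab, onsets.onsets[i]])

    summary = dict(summary)
    summary["config_digest"] = digest
    summary["config"] = config.to_dict()
    (outdir / f"{name}_summary.json").write_text(json.dumps(summary, indent=2, default=float))
    stimulus.save(outdir / f"{name}_stimulus")
    _write_panel(outdir / f"{name}_panel.png", stimulus, trace)


def _write_panel(path: Path, stimulus: stimuli.Stimulus, trace: TraceRecord) -> None:
    """Stimulus + final rate maps, in the style of the simulation figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    state = trace.final_state
    fig, axes = plt.subplots(1, 5, figsize=(16, 3.2))
    axes[0].imshow(stimulus.image, cmap="gray")
    axes[0].set_title("stimulus")
    from .dynamics import f_ho
    from .model import clip01

    for ax, area in zip(axes[1:4], ("V1", "V2", "V4")):
        m = clip01(state.v_b[area]).sum(axis=0)
        ax.imshow(m, cmap="magma")
        ax.set_title(f"{area} rate (θ-sum)")
    axes[4].imshow(f_ho(state.v_ho), cmap="magma")
    axes[4].set_title("HO rate")
    for ax in axes:
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ---------------------------------------------------------------------------
# scenario presets


def _narrow_wide_config(config: ExperimentConfig | None) -> ExperimentConfig:
    base = config or ExperimentConfig()
    if not base.stimulus:
        base.stimulus = {"generator": "narrow_wide_pair", "narrow_fraction": 1 / 3}
    return base


def _scenario_fig4_distance(config: ExperimentConfig, outdir: Path) -> dict:
    """Varying target-distractor distance: probe latencies + MI histogram."""
    config = _narrow_wide_config(config)
    stim = _make_stimulus(config.stimulus)
    trace = run_experiment(config, stimulus=stim)
    onsets = metrics.onset_times(trace, labels=stim.segment_labels)
    n = len(stim.target_path)
    probes = {f"P{i+1}": int(round(q * (n - 1))) for i, q in enumerate((0.25, 0.5, 0.75))}
    mi, n_excluded = metrics.mi_distribution(trace)
    summary = {
        "probe_onsets": {k: float(onsets.onsets[v]) for k, v in probes.items()},
        "tracing_time": metrics.tracing_time(onsets),
        "mi_mean": float(np.mean(mi)),
        "mi_median": float(np.median(mi)),
        "mi_hist": np.histogram(mi, bins=20, range=(-2, 2))[0].tolist(),
        "n_neurons": int(mi.size + n_excluded),
        "n_excluded": n_excluded,
    }
    _write_bundle(outdir, "fig4_distance", config, stim, trace, summary)
    return summary


def _scenario_fig5_sweep(
    config: ExperimentConfig, outdir: Path, fractions=None, conditions=("intact", "fb_v4_v2")
) -> dict:
    """Tracing time vs narrow fraction, intact and FB-lesioned."""
    fractions = list(fractions if fractions is not None else np.linspace(0.1, 0.9, 5))
    out: dict = {"fractions": fractions, "conditions": {}}
    for cond in conditions:
        times = []
        for frac in fractions:
            cfg = ExperimentConfig.from_dict(config.to_dict())
            cfg.stimulus = dict(
                config.stimulus or {"generator": "narrow_wide_pair"}, narrow_fraction=float(frac)
            )
            cfg.lesions = LESION_SETS[cond]
            stim = _make_stimulus(cfg.stimulus)
            trace = run_experiment(cfg, stimulus=stim)
            onsets = metrics.onset_times(trace, labels=stim.segment_labels)
            times.append(metrics.tracing_time(onsets))
            logger.info("fig5 %s fraction=%.2f tracing=%s", cond, frac, times[-1])
        slope, intercept = np.polyfit(fractions, times, 1)
        pred = np.polyval([slope, intercept], fractions)
        ss_res = float(np.sum((np.asarray(times) - pred) ** 2))
        ss_tot = float(np.sum((np.asarray(times) - np.mean(times)) ** 2))
        out["conditions"][cond] = {
            "tracing_times": [float(t) for t in times],
            "slope": float(slope),
            "intercept": float(intercept),
            "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        }
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "fig5_sweep_summary.json").write_text(json.dumps(out, indent=2))
    return out


def _scenario_fig6_lesions(config: ExperimentConfig, outdir: Path) -> dict:
    """The four-run lesion battery with per-segment speeds."""
    config = _narrow_wide_config(config)
    stim = _make_stimulus(config.stimulus)
    out: dict = {}
    for cond, spec in LESION_SETS.items():
        cfg = ExperimentConfig.from_dict(config.to_dict())
        cfg.lesions = list(spec)
        trace = run_experiment(cfg, stimulus=stim)
        speeds = segment_speeds(trace, stim)
        out[cond] = {
            "segment_speeds": {k: float(v) for k, v in speeds.items()},
            "steps_run": trace.meta["steps_run"],
        }
        logger.info("fig6 %s speeds=%s", cond, speeds)
        _write_bundle(outdir, f"fig6_{cond}", cfg, stim, trace, out[cond])
    (outdir / "fig6_lesions_summary.json").write_text(json.dumps(out, indent=2))
    return out


def _scenario_fig7_crossing(config: ExperimentConfig, outdir: Path) -> dict:
    """Seed either contour of a 90-degree crossing; report up-modulated
    fractions of both contours outside a junction neighbourhood."""
    base = config.stimulus or {"generator": "crossing", "angle_deg": 90.0}
    out: dict = {}
    for sid in ("Att1", "Att2"):
        cfg = ExperimentConfig.from_dict(config.to_dict())
        cfg.stimulus = dict(base, target="A" if sid == "Att1" else "B")
        cfg.seed_id = sid
        stim = _make_stimulus(cfg.stimulus)
        trace = run_experiment(cfg, stimulus=stim)
        out[sid] = crossing_summary(trace, stim)
        _write_bundle(outdir, f"fig7_{sid}", cfg, stim, trace, out[sid])
    (outdir / "fig7_crossing_summary.json").write_text(json.dumps(out, indent=2))
    return out


def crossing_summary(
    trace: TraceRecord, stim: stimuli.Stimulus, exclusion_px: float = 15.0
) -> dict:
    """Fraction of each contour up-modulated (MI > 0.2) outside the junction."""
    onsets = metrics.onset_times(trace)
    base = metrics.baseline_step(onsets)
    tser = trace.path_rates_sum
    mi_t = metrics.modulation_index(tser[-1], tser[base])
    path = np.asarray(stim.target_path)
    h, w = stim.image.shape
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    tmask = np.hypot(*(path - centre).T) > exclusion_px
    out = {"target_frac": float(np.nanmean((mi_t > 0.2)[tmask]))}
    fracs = []
    for k, dser in enumerate(trace.distractor_rates):
        dpath = np.asarray(stim.distractor_paths[k])
        dmask = np.hypot(*(dpath - centre).T) > exclusion_px
        mi_d = metrics.modulation_index(dser[-1], dser[base])
        fracs.append(float(np.nanmean((mi_d > 0.2)[dmask])))
    out["distractor_fracs"] = fracs
    return out


def _scenario_fig9_suite(config: ExperimentConfig, outdir: Path) -> dict:
    """Complex geometries: rings, spiral, dashed/solid lines, with
    arc-length-scaled speeds."""
    suite = {
        "lines15": {"generator": "parallel_lines", "length_px": 160, "distance_px": 15,
                    "image_shape": (120, 200)},
        "lines40": {"generator": "parallel_lines", "length_px": 160, "distance_px": 40,
                    "image_shape": (120, 200)},
        "dashed40": {"generator": "parallel_lines", "length_px": 160, "distance_px": 40,
                     "image_shape": (120, 200), "dashed": True},
        "singleRing30": {"generator": "rings", "radii": [30], "arc_deg": 240.0},
        "rings25": {"generator": "rings", "radii": [25, 40, 55], "seed_ring_index": 0,
                    "arc_deg": 240.0},
        "spiral": {"generator": "spiral", "spacing_px": 15, "start_radius": 6, "turns": 1.5},
    }
    out: dict = {}
    for name, sspec in suite.items():
        cfg = ExperimentConfig.from_dict(config.to_dict())
        cfg.stimulus = sspec
        stim = _make_stimulus(sspec)
        trace = run_experiment(cfg, stimulus=stim)
        onsets = metrics.onset_times(trace, labels=stim.segment_labels)
        profile = metrics.scaled_speeds(onsets, stim.target_path, probe_spacing=10)
        speeds = profile.pair_speeds[np.isfinite(profile.pair_speeds)]
        out[name] = {
            "tracing_time": metrics.tracing_time(onsets),
            "n_probes": int(len(profile.probe_indices)),
            "scaled_speed_median": float(np.median(speeds)) if speeds.size else None,
            "scaled_speed_iqr": (
                [float(np.percentile(speeds, 25)), float(np.percentile(speeds, 75))]
                if speeds.size
                else None
            ),
            "bound_fraction": float(np.mean(np.isfinite(onsets.onsets))),
        }
        logger.info("fig9 %s: %s", name, out[name])
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "fig9_suite_summary.json").write_text(json.dumps(out, indent=2))
    return out


SCENARIOS = {
    "fig4_distance": _scenario_fig4_distance,
    "fig5_sweep": _scenario_fig5_sweep,
    "fig6_lesions": _scenario_fig6_lesions,
    "fig7_crossing": _scenario_fig7_crossing,
    "fig9_suite": _scenario_fig9_suite,
}


def run_scenario(name: str, config: ExperimentConfig | None = None, **kwargs) -> dict:
    """Run a named scenario preset and write its output bundle."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    config = config or ExperimentConfig()
    outdir = Path(config.output_dir) / name
    return SCENARIOS[name](config, outdir, **kwargs)


# ---------------------------------------------------------------------------
# calibration


def calibrate(
    target_speeds: tuple = REFERENCE_SPEEDS["intact"],
    param_grid: dict | None = None,
    base_params: ModelParams | None = None,
    stimulus: stimuli.Stimulus | None = None,
    n_steps: int = 400,
) -> tuple[ModelParams, list]:
    """Grid search over a declared parameter subset minimising the squared
    error to the intact-condition segment speeds.

    ``param_grid`` maps (possibly nested, dot-separated) parameter names to
    candidate value lists, e.g. ``{"k_ho.V1": [8, 9, 10]}``.  Returns the
    best parameters and the full search log.  An empty grid returns the base
    parameters unchanged.  Raises ``RuntimeError`` if no grid point yields
    the wide > narrow speed ordering.
    """
    import itertools

    base_params = base_params or default_params()
    if not param_grid:
        return base_params, []
    if stimulus is None:
        stimulus = stimuli.make_narrow_wide_pair(1 / 3)

    keys = list(param_grid)
    log = []
    best = None
    for values in itertools.product(*(param_grid[k] for k in keys)):
        overrides: dict = {}
        for key, value in zip(keys, values):
            if "." in key:
                outer, inner = key.split(".", 1)
                overrides.setdefault(outer, {})[inner] = value
            else:
                overrides[key] = value
        params = base_params.override(overrides)
        net = build_network(params, stimulus.image.shape)
        trace = run(net, stimulus, n_steps=n_steps, record_every=0)
        speeds = segment_speeds(trace, stimulus)
        ordered = list(speeds.values())
        ok = (
            len(ordered) == 3
            and np.all(np.isfinite(ordered))
            and ordered[0] > ordered[1] < ordered[2]
        )
        sse = (
            float(np.sum((np.asarray(ordered) - np.asarray(target_speeds)) ** 2))
            if ok
            else float("inf")
        )
        log.append({"overrides": overrides, "speeds": speeds, "sse": sse, "ordered": bool(ok)})
        logger.info("calibrate %s -> %s (sse=%.4f)", overrides, speeds, sse)
        if best is None or sse < best[0]:
            best = (sse, params)
    if best is None or not np.isfinite(best[0]):
        raise RuntimeError(
            "calibration failed: no grid point produced the wide > narrow "
            "speed ordering; see the search log"
        )
    return best[1], log
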