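"""Evaluation metrics: modulation index, onset times, tracing speeds.

All latencies are in simulation steps (one synchronous sweep); speeds are in
neurons/step along the annotated path, or pixel/step after arc-length
scaling for curved geometries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dynamics import TraceRecord

__all__ = [
    "OnsetSeries",
    "SpeedProfile",
    "SMOOTHING_KERNEL",
    "modulation_index",
    "mi_distribution",
    "onset_times",
    "smooth_onsets",
    "speed_profile",
    "tracing_time",
    "scaled_speeds",
    "baseline_step",
]

# binomial smoothing kernel for onset times along the contour
SMOOTHING_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def modulation_index(r_att, r_base):
    """Normalised rate change ``2 (r_att - r_base) / (r_att + r_base)``.

    Values lie in [-2, 2].  Positions with zero activity in both conditions
    are excluded and return NaN.
    """
    r_att = np.asarray(r_att, dtype=float)
    r_base = np.asarray(r_base, dtype=float)
    total = r_att + r_base
    with np.errstate(divide="ignore", invalid="ignore"):
        mi = 2.0 * (r_att - r_base) / total
    return np.where(total > 0, mi, np.nan)


@dataclass
class OnsetSeries:
    """Per-position modulation-onset times along a target path."""

    positions: list  # (row, col) along the path
    onsets: np.ndarray  # step index of onset; NaN where activity never rises
    series: np.ndarray  # (T, n_path) theta-summed rate series used for detection
    labels: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.positions)

    def finite(self) -> np.ndarray:
        return np.isfinite(self.onsets)


@dataclass
class SpeedProfile:
    """Pairwise and per-segment tracing speeds."""

    probe_indices: np.ndarray  # path indices of the probes
    pair_speeds: np.ndarray  # speed per adjacent probe pair; NaN where masked
    segment_speeds: dict  # label -> 1/slope of per-segment onset regression
    segment_slopes: dict  # label -> regression slope (steps per neuron)
    tracing_time: float  # onset of the last path position
    units: str = "neurons/step"


def onset_times(trace: TraceRecord, labels: list | None = None) -> OnsetSeries:
    """Modulation-onset times along the recorded target path.

    Activity is summed over the orientation channels per retinotopic
    position; the onset is the first step at which it crosses 50% of its
    maximum across the trial.  Positions with zero peak activity never
    rise (NaN).
    """
    series = trace.path_rates_sum  # (T, n_path)
    peak = series.max(axis=0)
    onsets = np.full(series.shape[1], np.nan)
    for i in range(series.shape[1]):
        if peak[i] <= 0:
            continue
        hits = np.nonzero(series[:, i] >= 0.5 * peak[i])[0]
        onsets[i] = float(hits[0])
    positions = trace.meta.get("target_path", list(range(series.shape[1])))
    return OnsetSeries(
        positions=positions, onsets=onsets, series=series, labels=list(labels or [])
    )


def smooth_onsets(onsets: np.ndarray) -> np.ndarray:
    """Binomial smoothing along the contour.

    The ends are padded by odd reflection, which leaves affine onset
    profiles exactly unchanged (plain reflection would flatten the slope at
    the contour ends)."""
    padded = np.pad(np.asarray(onsets, dtype=float), 2, mode="reflect", reflect_type="odd")
    return np.convolve(padded, SMOOTHING_KERNEL, mode="valid")


def tracing_time(onsets: OnsetSeries) -> float:
    """Onset time of the last path position (NaN if it never modulates)."""
    return float(onsets.onsets[-1])


def speed_profile(
    onsets: OnsetSeries, probe_spacing: int = 1, segment_margin: int = 0
) -> SpeedProfile:
    """Instantaneous and per-segment tracing speeds from onset times.

    Pairwise speeds are inverses of smoothed-onset differences between
    probes ``probe_spacing`` path positions apart (divided by the number of
    neurons in between, so units stay neurons/step).  Non-positive smoothed
    differences are masked with a warning.  Per-segment speeds are inverse
    slopes of an ordinary least-squares fit of (unsmoothed) onset time
    against path index within each labelled segment; ``segment_margin``
    positions at each segment boundary can be dropped from the fits to
    guard against contour-end and taper transients.
    """
    t = onsets.onsets
    if not np.all(np.isfinite(t)):
        warnings.warn("onset series contains never-modulated positions")
    smoothed = smooth_onsets(t)
    idx = np.arange(0, len(t), probe_spacing)
    dt = np.diff(smoothed[idx]) / probe_spacing
    with np.errstate(divide="ignore"):
        speeds = 1.0 / dt
    bad = dt <= 0
    if np.any(bad & np.isfinite(dt)):
        warnings.warn(
            f"{int(np.sum(bad))} non-increasing smoothed onset difference(s); masked"
        )
    speeds = np.where(bad, np.nan, speeds)

    seg_speeds: dict = {}
    seg_slopes: dict = {}
    if onsets.labels:
        labels = np.asarray(onsets.labels)
        for lab in dict.fromkeys(onsets.labels):  # preserve path order
            sel = np.nonzero(labels == lab)[0]
            if segment_margin and len(sel) > 2 * segment_margin + 2:
                sel = sel[segment_margin:-segment_margin]
            sel = sel[np.isfinite(t[sel])]
            if len(sel) < 2:
                seg_speeds[lab] = np.nan
                seg_slopes[lab] = np.nan
                continue
            slope = np.polyfit(sel.astype(float), t[sel], 1)[0]
            seg_slopes[lab] = float(slope)
            seg_speeds[lab] = float(1.0 / slope) if slope != 0 else np.inf

    return SpeedProfile(
        probe_indices=idx,
        pair_speeds=speeds,
        segment_speeds=seg_speeds,
        segment_slopes=seg_slopes,
        tracing_time=tracing_time(onsets),
    )


def scaled_speeds(
    onsets: OnsetSeries,
    path_geometry: list,
    probe_spacing: int = 10,
) -> SpeedProfile:
    """Pairwise speeds scaled by arc length between probes (pixel/step).

    ``path_geometry`` are the (row, col) positions of the path; the distance
    between probes is the cumulative Euclidean arc length along it, so
    speeds on differently curved geometries become comparable.
    """
    pts = np.asarray(path_geometry, dtype=float)
    if len(pts) != len(onsets.onsets):
        raise ValueError("path_geometry must match the onset series length")
    seg = np.diff(pts, axis=0)
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    smoothed = smooth_onsets(onsets.onsets)
    idx = np.arange(0, len(smoothed), probe_spacing)
    dt = np.diff(smoothed[idx])
    dd = np.diff(arc[idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        speeds = dd / dt
    speeds = np.where(dt > 0, speeds, np.nan)
    profile = speed_profile(onsets, probe_spacing=probe_spacing)
    return SpeedProfile(
        probe_indices=idx,
        pair_speeds=speeds,
        segment_speeds=profile.segment_speeds,
        segment_slopes=profile.segment_slopes,
        tracing_time=profile.tracing_time,
        units="px/step",
    )


def baseline_step(onsets: OnsetSeries) -> int:
    """Default baseline epoch for the modulation index: the step just before
    the first path position's onset (after the base representation has
    formed, before the gate opens anywhere on the path)."""
    finite = onsets.onsets[np.isfinite(onsets.onsets)]
    if len(finite) == 0:
        raise ValueError("no position ever modulated; baseline epoch undefined")
    return max(int(finite.min()) - 1, 0)


def mi_distribution(
    trace: TraceRecord, base_step: int | None = None
) -> tuple[np.ndarray, int]:
    """Modulation indices of every (position, orientation) neuron on the path.

    Compares the final-step rates against the baseline epoch (default: the
    step before the first onset along the path).  Returns the finite MI
    values and the number of neurons excluded for zero activity in both
    conditions.
    """
    if base_step is None:
        base_step = baseline_step(onset_times(trace))
    r_base = trace.path_rates[base_step]  # (n_path, n_theta)
    r_att = trace.path_rates[-1]
    mi = modulation_index(r_att, r_base).ravel()
    n_excluded = int(np.sum(~np.isfinite(mi)))
    return mi[np.isfinite(mi)], n_excluded
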