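"""Deterministic stimulus generators for curve-tracing experiments.

Every generator returns a :class:`Stimulus`: a grayscale luminance image in
[0, 1] together with the attentional seed location(s) and a ground-truth
annotation of the target contour (used only by the evaluation metrics, never
by the model).

Coordinate convention: 0-based ``(row, col)`` integer pixel positions
everywhere; an ``(x, y)`` in prose maps to ``(col, row)``.  Contours are
rendered as anti-aliased strokes of configurable width (default 2 px), which
gives Gabor filters a stable, slightly smoothed edge to respond to.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Stimulus",
    "make_parallel_lines",
    "make_narrow_wide_pair",
    "make_crossing",
    "make_rings",
    "make_spiral",
    "make_pathfinder_like",
]

_SAMPLE_SPACING = 0.25  # px, dense resampling step for rendering


@dataclass
class Stimulus:
    """A luminance image plus evaluation annotations."""

    image: np.ndarray  # 2D float in [0, 1]
    seeds: list[tuple[str, tuple[int, int]]]  # (identifier, (row, col))
    target_path: list[tuple[int, int]]  # ordered (row, col) from the seed outward
    segment_labels: list[str]
    distractor_paths: list[list[tuple[int, int]]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        h, w = self.image.shape
        for r, c in self.target_path:
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"target path position {(r, c)} outside image")
        if len(self.segment_labels) != len(self.target_path):
            raise ValueError("segment_labels must match target_path length")

    def save(self, basepath: str | Path) -> None:
        """Write ``<basepath>.png`` (image) and ``<basepath>.json`` (annotations)."""
        import imageio.v3 as iio

        basepath = Path(basepath)
        iio.imwrite(
            basepath.with_suffix(".png"),
            (np.clip(self.image, 0, 1) * 255).round().astype(np.uint8),
        )
        sidecar = {
            "seeds": [[sid, list(pos)] for sid, pos in self.seeds],
            "target_path": [list(p) for p in self.target_path],
            "segment_labels": self.segment_labels,
            "distractor_paths": [[list(p) for p in path] for path in self.distractor_paths],
            "meta": self.meta,
        }
        basepath.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, basepath: str | Path) -> "Stimulus":
        import imageio.v3 as iio

        basepath = Path(basepath)
        image = iio.imread(basepath.with_suffix(".png")).astype(float) / 255.0
        d = json.loads(basepath.with_suffix(".json").read_text())
        return cls(
            image=image,
            seeds=[(sid, tuple(pos)) for sid, pos in d["seeds"]],
            target_path=[tuple(p) for p in d["target_path"]],
            segment_labels=d["segment_labels"],
            distractor_paths=[[tuple(p) for p in path] for path in d["distractor_paths"]],
            meta=d["meta"],
        )


# ---------------------------------------------------------------------------
# rendering helpers


def _resample(vertices: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline (N x 2, float row/col) at uniform arc length."""
    vertices = np.asarray(vertices, dtype=float)
    seg = np.diff(vertices, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    if total <= 0:
        return vertices[:1]
    n = max(int(round(total / spacing)), 1)
    t = np.linspace(0.0, total, n + 1)
    rows = np.interp(t, arclen, vertices[:, 0])
    cols = np.interp(t, arclen, vertices[:, 1])
    return np.column_stack([rows, cols])


def _pixel_path(vertices: np.ndarray) -> list[tuple[int, int]]:
    """Ordered, deduplicated, 8-connected integer path along a polyline."""
    samples = _resample(vertices, 0.5)
    path: list[tuple[int, int]] = []
    for r, c in np.rint(samples).astype(int):
        p = (int(r), int(c))
        if path and p == path[-1]:
            continue
        if path:
            pr, pc = path[-1]
            # fill any rounding gap to keep 8-connectivity
            while max(abs(p[0] - pr), abs(p[1] - pc)) > 1:
                pr += int(np.sign(p[0] - pr))
                pc += int(np.sign(p[1] - pc))
                if (pr, pc) != p:
                    path.append((pr, pc))
        path.append(p)
    return path


def _render(image: np.ndarray, samples: np.ndarray, width: float) -> None:
    """Anti-aliased stroke: luminance falls off linearly over the last pixel."""
    if len(samples) == 0:
        return
    h, w = image.shape
    pad = width / 2.0 + 1.5
    r0 = max(int(samples[:, 0].min() - pad), 0)
    r1 = min(int(samples[:, 0].max() + pad) + 1, h)
    c0 = max(int(samples[:, 1].min() - pad), 0)
    c1 = min(int(samples[:, 1].max() + pad) + 1, w)
    if r1 <= r0 or c1 <= c0:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist, _ = cKDTree(samples).query(pts, workers=-1)
    lum = np.clip(width / 2.0 + 0.5 - dist, 0.0, 1.0).reshape(rr.shape)
    np.maximum(image[r0:r1, c0:c1], lum, out=image[r0:r1, c0:c1])


def _dash_mask(n: int, spacing: float, dash_len: float, gap: float) -> np.ndarray:
    """Boolean mask over ``n`` uniformly spaced samples keeping dash segments."""
    arc = np.arange(n) * spacing
    return (arc % (dash_len + gap)) < dash_len


def _check_margin(vertices: np.ndarray, shape: tuple[int, int], margin: float) -> None:
    v = np.asarray(vertices, dtype=float)
    if (
        v[:, 0].min() < margin
        or v[:, 1].min() < margin
        or v[:, 0].max() > shape[0] - 1 - margin
        or v[:, 1].max() > shape[1] - 1 - margin
    ):
        raise ValueError(
            f"stimulus geometry exceeds image bounds {shape} with margin {margin}"
        )


# ---------------------------------------------------------------------------
# generators


def make_parallel_lines(
    length_px: int,
    distance_px: int,
    image_shape: tuple[int, int] = (160, 300),
    dashed: bool = False,
    dash_len: int = 10,
    gap: int = 6,
    width: float = 2.0,
    margin: float = 16.0,
) -> Stimulus:
    """Two parallel horizontal lines; the seed sits at the left end of the
    upper (target) line.  ``distance_px`` is the vertical separation."""
    if length_px <= 0:
        raise ValueError(f"length_px must be positive, got {length_px}")
    if distance_px < 1:
        raise ValueError(f"distance_px must be >= 1, got {distance_px}")
    h, w = image_shape
    r_target = (h - distance_px) // 2
    r_distr = r_target + distance_px
    c0 = (w - length_px) // 2
    target = np.array([[r_target, c0], [r_target, c0 + length_px]], dtype=float)
    distr = np.array([[r_distr, c0], [r_distr, c0 + length_px]], dtype=float)
    _check_margin(np.vstack([target, distr]), image_shape, margin)

    image = np.zeros(image_shape)
    for poly in (target, distr):
        samples = _resample(poly, _SAMPLE_SPACING)
        if dashed:
            samples = samples[_dash_mask(len(samples), _SAMPLE_SPACING, dash_len, gap)]
        _render(image, samples, width)

    path = _pixel_path(target)
    return Stimulus(
        image=image,
        seeds=[("Att", path[0])],
        target_path=path,
        segment_labels=["line"] * len(path),
        distractor_paths=[_pixel_path(distr)],
        meta={
            "generator": "parallel_lines",
            "length_px": length_px,
            "distance_px": distance_px,
            "dashed": dashed,
            "dash_len": dash_len,
            "gap": gap,
            "width": width,
        },
    )


def make_narrow_wide_pair(
    narrow_fraction: float,
    wide_dist: int = 40,
    narrow_dist: int = 15,
    image_shape: tuple[int, int] = (140, 280),
    length_px: int = 240,
    transition_px: int = 50,
    width: float = 2.0,
    margin: float = 16.0,
) -> Stimulus:
    """Target/distractor line pair whose separation narrows in the middle.

    The separation is ``wide_dist`` over the outer ``(1 - narrow_fraction)``
    of the length (split equally) and ``narrow_dist`` over the central
    ``narrow_fraction``, with linear tapers of ``transition_px``.  Segment
    labels ``wide1`` / ``narrow`` / ``wide2`` split at the taper midpoints.
    The seed sits at the left (wide) end of the target line.
    """
    if not 0.0 <= narrow_fraction <= 1.0:
        raise ValueError(f"narrow_fraction must lie in [0, 1], got {narrow_fraction}")
    if narrow_dist >= wide_dist:
        raise ValueError("narrow_dist must be smaller than wide_dist")
    h, w = image_shape
    r_target = (h - wide_dist) // 2
    c0 = (w - length_px) // 2
    xs = np.arange(length_px + 1, dtype=float)

    narrow_len = narrow_fraction * length_px
    s1 = (length_px - narrow_len) / 2.0  # start of narrow section
    s2 = s1 + narrow_len
    half_t = transition_px / 2.0

    def separation(x: np.ndarray) -> np.ndarray:
        # linear tapers; kept long by default so the distractor's direction
        # changes stay gentle (steep corners read out as localized
        # multi-orientation energy the narrow-wide manipulation is not
        # meant to probe)
        down = np.clip((x - (s1 - half_t)) / transition_px, 0.0, 1.0)
        up = np.clip((x - (s2 - half_t)) / transition_px, 0.0, 1.0)
        return wide_dist + (narrow_dist - wide_dist) * (down - up)

    if narrow_fraction == 0.0:
        sep = np.full_like(xs, float(wide_dist))
    elif narrow_fraction == 1.0:
        sep = np.full_like(xs, float(narrow_dist))
    else:
        sep = separation(xs)

    target = np.column_stack([np.full_like(xs, float(r_target)), c0 + xs])
    distr = np.column_stack([r_target + sep, c0 + xs])
    _check_margin(np.vstack([target, distr]), image_shape, margin)

    image = np.zeros(image_shape)
    _render(image, _resample(target, _SAMPLE_SPACING), width)
    _render(image, _resample(distr, _SAMPLE_SPACING), width)

    path = _pixel_path(target)
    labels = []
    for r, c in path:
        x = c - c0
        if narrow_fraction == 0.0:
            labels.append("wide1")
        elif x < s1:
            labels.append("wide1")
        elif x < s2:
            labels.append("narrow")
        else:
            labels.append("wide2")
    return Stimulus(
        image=image,
        seeds=[("Att", path[0])],
        target_path=path,
        segment_labels=labels,
        distractor_paths=[_pixel_path(distr)],
        meta={
            "generator": "narrow_wide_pair",
            "narrow_fraction": narrow_fraction,
            "wide_dist": wide_dist,
            "narrow_dist": narrow_dist,
            "length_px": length_px,
            "transition_px": transition_px,
            "width": width,
        },
    )


def make_crossing(
    angle_deg: float,
    image_shape: tuple[int, int] = (180, 180),
    length_px: int = 120,
    width: float = 2.0,
    margin: float = 16.0,
    target: str = "A",
) -> Stimulus:
    """Two contours crossing at their midpoints.

    Contour A is horizontal; contour B crosses it at ``angle_deg``.  Seeds
    ``Att1`` (left end of A) and ``Att2`` (an end of B) are both annotated;
    ``target`` selects which contour carries the target annotation.
    """
    if not 0.0 < angle_deg < 180.0:
        raise ValueError(f"angle_deg must lie in (0, 180), got {angle_deg}")
    h, w = image_shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    half = length_px / 2.0
    a = np.deg2rad(angle_deg)
    line_a = np.array([[cr, cc - half], [cr, cc + half]])
    dr, dc = np.sin(a) * half, np.cos(a) * half
    line_b = np.array([[cr - dr, cc - dc], [cr + dr, cc + dc]])
    _check_margin(np.vstack([line_a, line_b]), image_shape, margin)

    image = np.zeros(image_shape)
    _render(image, _resample(line_a, _SAMPLE_SPACING), width)
    _render(image, _resample(line_b, _SAMPLE_SPACING), width)

    path_a = _pixel_path(line_a)
    path_b = _pixel_path(line_b)
    if target == "A":
        tgt, dis = path_a, path_b
    elif target == "B":
        tgt, dis = path_b, path_a
    else:
        raise ValueError("target must be 'A' or 'B'")
    return Stimulus(
        image=image,
        seeds=[("Att1", path_a[0]), ("Att2", path_b[0])],
        target_path=tgt,
        segment_labels=["line"] * len(tgt),
        distractor_paths=[dis],
        meta={
            "generator": "crossing",
            "angle_deg": angle_deg,
            "length_px": length_px,
            "width": width,
            "target": target,
        },
    )


def make_rings(
    radii: list[int],
    seed_ring_index: int = 0,
    arc_deg: float = 360.0,
    image_shape: tuple[int, int] | None = None,
    width: float = 2.0,
    margin: float = 16.0,
) -> Stimulus:
    """Concentric ring (segments); the seed sits on the designated ring."""
    radii = list(radii)
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly increasing")
    if not 0.0 < arc_deg <= 360.0:
        raise ValueError(f"arc_deg must lie in (0, 360], got {arc_deg}")
    if not 0 <= seed_ring_index < len(radii):
        raise ValueError("seed_ring_index out of range")
    rmax = radii[-1]
    if image_shape is None:
        side = int(2 * (rmax + margin)) + 1
        image_shape = (side, side)
    h, w = image_shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0

    # arcs start at angle 0 (rightmost point) and run counter-clockwise
    def arc_vertices(radius: float) -> np.ndarray:
        n = max(int(np.deg2rad(arc_deg) * radius / 0.5), 8)
        phi = np.linspace(0.0, np.deg2rad(arc_deg), n + 1)
        if arc_deg == 360.0:
            phi = phi[:-1]
            phi = np.concatenate([phi, phi[:1]])  # close the ring
        return np.column_stack([cr - radius * np.sin(phi), cc + radius * np.cos(phi)])

    image = np.zeros(image_shape)
    paths = []
    for radius in radii:
        verts = arc_vertices(radius)
        _check_margin(verts, image_shape, margin)
        _render(image, _resample(verts, _SAMPLE_SPACING), width)
        paths.append(_pixel_path(verts))

    tgt = paths[seed_ring_index]
    distractors = [p for i, p in enumerate(paths) if i != seed_ring_index]
    return Stimulus(
        image=image,
        seeds=[("Att", tgt[0])],
        target_path=tgt,
        segment_labels=["ring"] * len(tgt),
        distractor_paths=distractors,
        meta={
            "generator": "rings",
            "radii": radii,
            "seed_ring_index": seed_ring_index,
            "arc_deg": arc_deg,
            "width": width,
        },
    )


def make_spiral(
    spacing_px: int = 15,
    start_radius: int = 6,
    turns: float = 2.0,
    image_shape: tuple[int, int] | None = None,
    width: float = 2.0,
    margin: float = 16.0,
) -> Stimulus:
    """Two interleaved Archimedean spiral arms ``spacing_px`` apart radially.

    The target arm carries the seed at its inner end; the second arm (offset
    by half a turn) is the distractor.
    """
    if turns <= 0:
        raise ValueError(f"turns must be positive, got {turns}")
    if spacing_px < 1:
        raise ValueError(f"spacing_px must be >= 1, got {spacing_px}")
    # adjacent lines alternate between arms, so each arm grows 2*spacing per turn
    b = 2.0 * spacing_px / (2.0 * np.pi)
    phi_max = 2.0 * np.pi * turns
    rmax = start_radius + spacing_px + b * phi_max
    if image_shape is None:
        side = int(2 * (rmax + margin)) + 1
        image_shape = (side, side)
    h, w = image_shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0

    def arm(radial_offset: float) -> np.ndarray:
        n = max(int(phi_max / 0.004), 64)
        phi = np.linspace(0.0, phi_max, n)
        r = start_radius + radial_offset + b * phi
        return np.column_stack([cr - r * np.sin(phi), cc + r * np.cos(phi)])

    target_verts = arm(0.0)
    distr_verts = arm(float(spacing_px))
    _check_margin(np.vstack([target_verts, distr_verts]), image_shape, margin)
    image = np.zeros(image_shape)
    _render(image, _resample(target_verts, _SAMPLE_SPACING), width)
    _render(image, _resample(distr_verts, _SAMPLE_SPACING), width)

    path = _pixel_path(target_verts)
    return Stimulus(
        image=image,
        seeds=[("Att", path[0])],
        target_path=path,
        segment_labels=["spiral"] * len(path),
        distractor_paths=[_pixel_path(distr_verts)],
        meta={
            "generator": "spiral",
            "spacing_px": spacing_px,
            "start_radius": start_radius,
            "turns": turns,
            "width": width,
        },
    )


def make_pathfinder_like(
    n_distractors: int,
    dash_len: int = 8,
    rng_seed: int = 0,
    image_shape: tuple[int, int] = (200, 200),
    gap: int = 6,
    width: float = 2.0,
    margin: float = 16.0,
    target_len: float = 140.0,
    distractor_len: float = 60.0,
    min_sep: float = 12.0,
    max_turn: float = 0.08,
) -> Stimulus:
    """Random field of dashed, smoothly curving lines in the style of the
    Pathfinder benchmark; a bright dot marks the seed end of the target curve.

    This emulates the stimulus style only (curvature-bounded random walks),
    not the statistics of the published dataset.  All randomness flows from
    ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    h, w = image_shape

    def random_walk(
        length: float, existing: list[np.ndarray], keep_fraction: float = 0.7
    ) -> np.ndarray | None:
        """Curvature-bounded random walk avoiding existing curves.

        A walk that hits the image margin or another curve early is kept if
        it reached ``keep_fraction`` of the requested length; returns None
        if no acceptable walk is found.
        """
        step = 1.0
        n_steps = int(length / step)
        for _ in range(200):
            pos = np.array(
                [
                    rng.uniform(margin + 10, h - margin - 10),
                    rng.uniform(margin + 10, w - margin - 10),
                ]
            )
            heading = rng.uniform(0, 2 * np.pi)
            pts = [pos.copy()]
            tree = cKDTree(np.vstack(existing)) if existing else None
            for _ in range(n_steps):
                heading += rng.uniform(-max_turn, max_turn)
                nxt = pos + step * np.array([np.sin(heading), np.cos(heading)])
                if not (
                    margin < nxt[0] < h - 1 - margin and margin < nxt[1] < w - 1 - margin
                ):
                    break
                if tree is not None and tree.query(nxt)[0] < min_sep:
                    break
                pos = nxt
                pts.append(pos.copy())
            if len(pts) >= keep_fraction * n_steps:
                return np.array(pts)
        return None

    curves: list[np.ndarray] = []
    target_verts = random_walk(target_len, curves)
    if target_verts is None:
        raise RuntimeError("failed to place target curve; relax geometry parameters")
    curves.append(target_verts)
    distractor_verts = []
    for _ in range(n_distractors):
        c = random_walk(distractor_len, curves)
        if c is not None:
            curves.append(c)
            distractor_verts.append(c)

    image = np.zeros(image_shape)
    for verts in curves:
        samples = _resample(verts, _SAMPLE_SPACING)
        keep = _dash_mask(len(samples), _SAMPLE_SPACING, dash_len, gap)
        _render(image, samples[keep], width)

    path = _pixel_path(target_verts)
    # bright dot indexing the target line at the seed
    _render(image, np.array([path[0]], dtype=float), 5.0)

    return Stimulus(
        image=image,
        seeds=[("Att", path[0])],
        target_path=path,
        segment_labels=["curve"] * len(path),
        distractor_paths=[_pixel_path(v) for v in distractor_verts],
        meta={
            "generator": "pathfinder_like",
            "n_distractors": n_distractors,
            "n_placed_distractors": len(distractor_verts),
            "dash_len": dash_len,
            "gap": gap,
            "rng_seed": rng_seed,
            "dashed": True,
            "width": width,
        },
    )
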