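"""Channel kernels of the network model.

Every connection between two model areas is realised by a space-feature
separable kernel ``K(x, y, theta) = K(x, y) * K(theta)``.  The spatial part
is a Gabor (feedforward / feedback), a Gaussian (inhibitory surround) or a
uniform box (thalamo-cortical binding channels); the feature part acts on the
orientation axis, which is circular with period pi.

Normalisation conventions:

* Gabor kernels (FF / FB) have their positive and negative parts separately
  normalised to sums of 1, which removes the DC component.
* The composite inhibitory kernel (Gaussian x uniform) sums to 1.
* B1 kernels (cortex -> interfacing module) are uniform boxes over a spatial
  neighbourhood and all orientation channels, normalised to sum 1 (a local
  space-feature average of the source rates).
* B2 kernels (interfacing module -> cortex) are purely spatial uniform boxes
  normalised to sum 0.5; the interfacing module codes no orientation.

Grid side length of Gaussian/Gabor kernels is ``1 + 2 * ceil(5 * sigma)`` to
avoid cut-off artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Kernel",
    "orientation_set",
    "gabor",
    "make_ff_kernel",
    "make_inh_kernel",
    "make_fb_kernels",
    "make_b1_kernel",
    "make_b2_kernel",
    "save_kernels",
    "kernel_montage",
]


def orientation_set(n_theta: int) -> np.ndarray:
    """The ``n_theta`` canonical orientations, equally spaced on [0, pi)."""
    return np.arange(n_theta) * (np.pi / n_theta)


def _grid(sigma: float) -> np.ndarray:
    """Coordinate offsets for a kernel of side ``1 + 2*ceil(5*sigma)``."""
    r = int(math.ceil(5.0 * sigma))
    return np.arange(-r, r + 1, dtype=float)


def gabor(sigma: float, theta: float) -> np.ndarray:
    """Even-phase Gabor, aspect ratio 1, wavelength ``2*pi*sigma``.

    ``theta`` is the preferred *contour* orientation: the carrier modulates
    along the contour normal, so the excitatory ridge is collinear with a bar
    of orientation ``theta``.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    c = _grid(sigma)
    yy, xx = np.meshgrid(c, c, indexing="ij")
    # normal direction to a contour of orientation theta
    xn = xx * math.cos(theta + math.pi / 2.0) + yy * math.sin(theta + math.pi / 2.0)
    envelope = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    carrier = np.cos(xn / sigma)  # wavelength 2*pi*sigma
    return envelope * carrier


def _split_normalise(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positive/negative parts of ``g``, each normalised to sum 1."""
    pos = np.where(g > 0, g, 0.0)
    neg = np.where(g < 0, -g, 0.0)
    return pos / pos.sum(), neg / neg.sum()


def _gaussian(sigma: float) -> np.ndarray:
    c = _grid(sigma)
    yy, xx = np.meshgrid(c, c, indexing="ij")
    g = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return g / g.sum()


def cosine_halfwave(n_theta: int, i: int) -> np.ndarray:
    """Rectified cosine tuning over the pi-periodic orientation circle.

    The angular difference is doubled before the cosine so that the weight is
    1 at the preferred orientation and reaches 0 at the orthogonal one.
    Entry ``j`` weighs source channel ``theta_j`` for target channel
    ``theta_i``.
    """
    thetas = orientation_set(n_theta)
    d = thetas - thetas[i]
    return np.maximum(np.cos(2.0 * d), 0.0)


@dataclass
class Kernel:
    """A space-feature separable channel kernel.

    ``spatial`` is either a single 2D grid (orientation-independent channels)
    or a stack of per-target-orientation grids, shape ``(n_theta, k, k)``.
    ``feature`` holds per-target-orientation weight vectors over the source
    orientation channels, shape ``(n_theta, n_theta)``; ``None`` for the
    purely spatial B2 kernel.
    """

    spatial: np.ndarray
    feature: np.ndarray | None
    channel_type: str  # FF | Inh | FB_pos | FB_neg | B1 | B2
    norm_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.spatial)):
            raise ValueError("kernel spatial grid contains non-finite values")
        if self.feature is not None and not np.all(np.isfinite(self.feature)):
            raise ValueError("kernel feature weights contain non-finite values")

    @property
    def n_theta(self) -> int | None:
        return None if self.feature is None else self.feature.shape[1]


def make_ff_kernel(sigma: float, n_theta: int, n_source: int | None = None) -> Kernel:
    """Feedforward kernel stack: Gabor in space, Dirac on the feature axis.

    The Dirac feature kernel means the channel for target orientation
    ``theta_i`` reads only the source channel of the same orientation.  For a
    single-channel source (the luminance input) every target orientation
    reads that one channel.
    """
    if n_source is None:
        n_source = n_theta
    thetas = orientation_set(n_theta)
    grids = []
    for th in thetas:
        pos, neg = _split_normalise(gabor(sigma, th))
        grids.append(pos - neg)
    spatial = np.stack(grids)
    feature = np.ones((n_theta, 1)) if n_source == 1 else np.eye(n_theta)
    return Kernel(spatial, feature, "FF", {"sigma": sigma, "pos_sum": 1.0, "neg_sum": 1.0})


def make_inh_kernel(sigma: float, n_theta: int) -> Kernel:
    """Inhibitory surround: Gaussian in space, uniform over all orientations.

    The composite (spatial x feature) kernel sums to 1.
    """
    spatial = _gaussian(sigma)
    feature = np.full((n_theta, n_theta), 1.0 / n_theta)
    return Kernel(spatial, feature, "Inh", {"sigma": sigma, "total_sum": 1.0})


def make_fb_kernels(sigma: float, n_theta: int) -> tuple[Kernel, Kernel]:
    """Feedback kernel pair.

    The positive Gabor part is paired with a rectified-cosine feature kernel
    (collinear, like-oriented context excites); the negative part with a
    uniform feature kernel (off-axis context of any orientation suppresses).
    Both spatial parts are normalised to sums of 1; the suppressive pathway is
    scaled by ``xi`` at application time.
    """
    thetas = orientation_set(n_theta)
    pos_grids, neg_grids, feats = [], [], []
    for i, th in enumerate(thetas):
        pos, neg = _split_normalise(gabor(sigma, th))
        pos_grids.append(pos)
        neg_grids.append(neg)
        feats.append(cosine_halfwave(n_theta, i))
    kpos = Kernel(np.stack(pos_grids), np.stack(feats), "FB_pos", {"sigma": sigma})
    kneg = Kernel(
        np.stack(neg_grids),
        np.full((n_theta, n_theta), 1.0 / n_theta),
        "FB_neg",
        {"sigma": sigma},
    )
    return kpos, kneg


def make_b1_kernel(rho_x: int, n_theta: int) -> Kernel:
    """Binding channel into the interfacing module: uniform box over a
    ``rho_x x rho_x`` spatial neighbourhood and all orientation channels,
    composite sum 1."""
    if rho_x < 1:
        raise ValueError(f"rho_x must be >= 1, got {rho_x}")
    spatial = np.full((rho_x, rho_x), 1.0 / (rho_x * rho_x))
    feature = np.full((1, n_theta), 1.0 / n_theta)
    return Kernel(spatial, feature, "B1", {"rho_x": rho_x, "total_sum": 1.0})


def save_kernels(kernels: dict, path) -> None:
    """Export a named set of kernels to HDF5 for inspection.

    ``kernels`` maps names to :class:`Kernel` instances; spatial grids and
    feature weights are stored per kernel together with the type tag and
    normalisation metadata.
    """
    import json

    import h5py

    with h5py.File(path, "w") as f:
        for name, k in kernels.items():
            grp = f.create_group(name)
            grp.create_dataset("spatial", data=k.spatial)
            if k.feature is not None:
                grp.create_dataset("feature", data=k.feature)
            grp.attrs["channel_type"] = k.channel_type
            grp.attrs["norm_meta"] = json.dumps(k.norm_meta)


def kernel_montage(kernel: Kernel, path) -> None:
    """Render the per-orientation spatial grids of a kernel as a PNG montage."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grids = kernel.spatial if kernel.spatial.ndim == 3 else kernel.spatial[None]
    n = len(grids)
    cols = min(n, 6)
    rows = -(-n // cols)
    fig, axes = plt.subplots(rows, cols, figsize=(2.0 * cols, 2.0 * rows), squeeze=False)
    vmax = np.max(np.abs(grids))
    for i, ax in enumerate(axes.ravel()):
        ax.set_xticks([])
        ax.set_yticks([])
        if i < n:
            ax.imshow(grids[i], cmap="RdBu_r", vmin=-vmax, vmax=vmax)
            ax.set_title(f"θ[{i}]", fontsize=8)
        else:
            ax.axis("off")
    fig.suptitle(kernel.channel_type)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def make_b2_kernel(rho_x: int) -> Kernel:
    """Gating channel out of the interfacing module: purely spatial uniform
    box normalised to sum 0.5 (the interfacing module codes no feature)."""
    if rho_x < 1:
        raise ValueError(f"rho_x must be >= 1, got {rho_x}")
    spatial = np.full((rho_x, rho_x), 0.5 / (rho_x * rho_x))
    return Kernel(spatial, None, "B2", {"rho_x": rho_x, "total_sum": 0.5})
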