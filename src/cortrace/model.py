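"""Network graph: areas, scale-space geometry, the convolve-resize channel
operator, the connectivity table and lesioning.

The visual-cortex module is a scale-space hierarchy (V1, V2, V4 at relative
sizes 1, 0.5, 0.25 of the input) of orientation maps; the interfacing module
(HO, the higher-order thalamic map) is a single featureless retinotopic map
at relative size 0.66.  A channel applies its kernel by convolving the source
rate field at the source resolution (zero padding in space, circular on the
orientation axis), resizing the result to the target map with linear
interpolation, and passing it through ``f(x) = min(max(x, 0), 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve
from skimage.transform import resize as _sk_resize

from . import kernels as K

__all__ = [
    "AreaSpec",
    "Channel",
    "LesionSpec",
    "Network",
    "CONNECTIVITY",
    "apply_channel",
    "apply_fb_channel",
    "build_network",
    "lesion",
]

# relative map sizes with respect to the input
REL_SIZES = {"Inp": 1.0, "V1": 1.0, "V2": 0.5, "V4": 0.25, "HO": 0.66}

# the network connectivity table: (source, target, channel type)
CONNECTIVITY: tuple[tuple[str, str, str], ...] = (
    ("Inp", "V1", "FF"),
    ("V1", "V1", "Inh"),
    ("V1", "V2", "FF"),
    ("V1", "HO", "B1"),
    ("V2", "V1", "FB"),
    ("V2", "V2", "Inh"),
    ("V2", "V4", "FF"),
    ("V2", "HO", "B1"),
    ("V4", "V2", "FB"),
    ("V4", "V4", "Inh"),
    ("V4", "HO", "B1"),
    ("HO", "V1", "B2"),
    ("HO", "V2", "B2"),
    ("HO", "V4", "B2"),
    ("S", "HO", "B1"),
)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class AreaSpec:
    name: str
    rel_size: float
    n_features: int
    shape: tuple[int, int]


@dataclass
class Channel:
    source: str
    target: str
    channel_type: str  # FF | Inh | FB | B1 | B2
    kernel: K.Kernel | None = None
    kernel_neg: K.Kernel | None = None  # suppressive pathway of FB channels
    enabled: bool = True

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.channel_type, self.source, self.target)


@dataclass(frozen=True)
class LesionSpec:
    """Channels to disable, named as (channel_type, source, target) triples."""

    triples: tuple[tuple[str, str, str], ...] = ()

    def __post_init__(self) -> None:
        valid = {(c, s, t) for s, t, c in CONNECTIVITY}
        for triple in self.triples:
            if tuple(triple) not in valid:
                raise ValueError(f"unknown channel {triple}; must be one of {sorted(valid)}")

    @classmethod
    def parse(cls, specs: list[str]) -> "LesionSpec":
        """Parse ``TYPE:SRC:TGT`` strings, e.g. ``FB:V4:V2``."""
        return cls(tuple(tuple(s.split(":")) for s in specs))


def resize_field(field: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Linear-interpolation resize (align-corners-false convention)."""
    if field.shape == tuple(shape):
        return field
    return _sk_resize(
        field, shape, order=1, mode="edge", anti_aliasing=False, preserve_range=True
    )


def clip01(x: np.ndarray) -> np.ndarray:
    """The node input nonlinearity: rectification with saturation ceiling."""
    return np.clip(x, 0.0, 1.0)


def apply_channel(
    kernel: K.Kernel,
    source_rates: np.ndarray,
    target_shape: tuple[int, int],
    clip: bool = True,
) -> np.ndarray:
    """Apply a space-feature separable kernel to a source rate field.

    ``source_rates`` has shape ``(n_src_channels, H, W)`` (or ``(H, W)`` for a
    featureless source).  The feature contraction is a circular weighting
    over orientation channels; the spatial convolution zero-pads; the result
    is resized to ``target_shape`` and clipped to [0, 1] unless ``clip`` is
    False.  Returns ``(n_tgt_channels, h, w)`` or ``(h, w)`` for a
    featureless target (B1/B2).
    """
    rates = np.asarray(source_rates, dtype=float)
    if kernel.feature is None:
        if rates.ndim != 2:
            raise ValueError("purely spatial kernel expects a 2D source field")
        out = fftconvolve(rates, kernel.spatial, mode="same")
        out = resize_field(out, target_shape)
        return clip01(out) if clip else out

    if rates.ndim == 2:
        rates = rates[None]
    if rates.shape[0] != kernel.feature.shape[1]:
        raise ValueError(
            f"source has {rates.shape[0]} channels, kernel expects {kernel.feature.shape[1]}"
        )
    mixed = np.einsum("ts,shw->thw", kernel.feature, rates)
    spatial = kernel.spatial
    if spatial.ndim == 2:
        spatial = spatial[None]
    out = fftconvolve(mixed, spatial, mode="same", axes=(1, 2))
    if out.shape[1:] != tuple(target_shape):
        out = np.stack([resize_field(ch, target_shape) for ch in out])
    if out.shape[0] == 1:
        out = out[0]
    return clip01(out) if clip else out


def apply_fb_channel(
    kpos: K.Kernel,
    kneg: K.Kernel,
    xi: float,
    source_rates: np.ndarray,
    target_shape: tuple[int, int],
) -> np.ndarray:
    """Feedback conductance ``g+ + xi * g-``.

    Each pathway is applied (and clipped) separately; the combination is not
    clipped, so the suppressive pathway (``xi < 0``) can drive the apical
    conductance negative.
    """
    g_pos = apply_channel(kpos, source_rates, target_shape, clip=True)
    g_neg = apply_channel(kneg, source_rates, target_shape, clip=True)
    return g_pos + xi * g_neg


class Network:
    """Areas plus instantiated channels for a given input shape."""

    def __init__(self, params, input_shape: tuple[int, int]):
        from .config import ModelParams

        if not isinstance(params, ModelParams):
            raise TypeError("params must be a ModelParams instance")
        params.validate()
        self.params = params
        self.input_shape = tuple(input_shape)
        n_theta = params.n_theta
        self.areas: dict[str, AreaSpec] = {}
        for name, s in REL_SIZES.items():
            shape = (
                _round_half_up(input_shape[0] * s),
                _round_half_up(input_shape[1] * s),
            )
            n_feat = n_theta if name in ("V1", "V2", "V4") else 1
            self.areas[name] = AreaSpec(name, s, n_feat, shape)
        self.channels: list[Channel] = [self._make_channel(*c) for c in CONNECTIVITY]

    def _make_channel(self, src: str, tgt: str, ctype: str) -> Channel:
        p = self.params
        if ctype == "FF":
            n_source = 1 if src == "Inp" else p.n_theta
            k = K.make_ff_kernel(p.sigma_ff[f"{src}->{tgt}"], p.n_theta, n_source)
            return Channel(src, tgt, ctype, kernel=k)
        if ctype == "Inh":
            return Channel(src, tgt, ctype, kernel=K.make_inh_kernel(p.sigma_inh[tgt], p.n_theta))
        if ctype == "FB":
            kp, kn = K.make_fb_kernels(p.sigma_fb[f"{src}->{tgt}"], p.n_theta)
            return Channel(src, tgt, ctype, kernel=kp, kernel_neg=kn)
        if ctype == "B1":
            if src == "S":
                return Channel(src, tgt, ctype, kernel=None)  # external task input
            return Channel(src, tgt, ctype, kernel=K.make_b1_kernel(p.rho_b1[src], p.n_theta))
        if ctype == "B2":
            return Channel(src, tgt, ctype, kernel=K.make_b2_kernel(p.rho_b2[tgt]))
        raise ValueError(f"unknown channel type {ctype}")

    def channel(self, ctype: str, src: str, tgt: str) -> Channel:
        for ch in self.channels:
            if ch.key == (ctype, src, tgt):
                return ch
        raise KeyError((ctype, src, tgt))

    def describe(self) -> dict:
        """JSON-serialisable provenance record of the network structure."""
        return {
            "input_shape": list(self.input_shape),
            "areas": {
                a.name: {
                    "rel_size": a.rel_size,
                    "n_features": a.n_features,
                    "shape": list(a.shape),
                }
                for a in self.areas.values()
            },
            "channels": [
                {
                    "source": ch.source,
                    "target": ch.target,
                    "type": ch.channel_type,
                    "enabled": ch.enabled,
                }
                for ch in self.channels
            ],
        }


def build_network(params, input_shape: tuple[int, int]) -> Network:
    """Allocate all areas and instantiate every channel of the connectivity
    table (V4 receives no feedback; the task module S is an external input)."""
    return Network(params, input_shape)


def lesion(network: Network, spec: LesionSpec) -> Network:
    """Return a copy of the network with the named channels disabled.

    A disabled channel contributes an identically-zero conductance; nothing
    else changes.
    """
    import copy

    out = copy.copy(network)
    out.channels = [replace(ch) for ch in network.channels]
    for triple in spec.triples:
        found = False
        for ch in out.channels:
            if ch.key == tuple(triple):
                ch.enabled = False
                found = True
        if not found:  # pragma: no cover - LesionSpec already validates
            raise KeyError(triple)
    return out
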