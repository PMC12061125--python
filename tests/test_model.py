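import numpy as np
import pytest

import cortrace as ct
from cortrace import kernels as K
from cortrace.model import (
    CONNECTIVITY,
    LesionSpec,
    apply_channel,
    apply_fb_channel,
    build_network,
    lesion,
    resize_field,
)


def brute_force_channel(kernel, rates):
    """Direct-summation oracle for the space-feature kernel application:
    circular contraction on the orientation axis, zero-padded true
    convolution in space, no resize, no clipping."""
    n_tgt, n_src = kernel.feature.shape
    _, h, w = rates.shape
    spatial = kernel.spatial if kernel.spatial.ndim == 3 else np.tile(kernel.spatial, (n_tgt, 1, 1))
    kh, kw = spatial.shape[1:]
    rh, rw = kh // 2, kw // 2
    out = np.zeros((n_tgt, h, w))
    for t in range(n_tgt):
        for i in range(h):
            for j in range(w):
                acc = 0.0
                for s in range(n_src):
                    for u in range(kh):
                        for v in range(kw):
                            ii = i - (u - rh)  # true convolution flips the kernel
                            jj = j - (v - rw)
                            if 0 <= ii < h and 0 <= jj < w:
                                acc += kernel.feature[t, s] * spatial[t, u, v] * rates[s, ii, jj]
                out[t, i, j] = acc
    return out


def test_apply_channel_matches_direct_summation_oracle():
    rng = np.random.default_rng(0)
    rates = rng.random((4, 9, 9))
    kernel = K.Kernel(
        spatial=rng.standard_normal((4, 5, 5)),
        feature=rng.random((4, 4)),
        channel_type="FF",
    )
    got = apply_channel(kernel, rates, (9, 9), clip=False)
    want = brute_force_channel(kernel, rates)
    assert np.max(np.abs(got - want)) < 1e-10


def test_dirac_kernel_at_matched_size_is_identity():
    rng = np.random.default_rng(1)
    rates = rng.random((3, 8, 8)) * 2 - 0.5  # includes values outside [0, 1]
    kernel = K.Kernel(spatial=np.ones((1, 1)), feature=np.eye(3), channel_type="FF")
    out = apply_channel(kernel, rates, (8, 8))
    assert np.allclose(out, np.clip(rates, 0, 1))


def test_constant_field_through_sum_one_kernel_is_preserved():
    kernel = K.make_inh_kernel(1.0, 6)
    rates = np.full((6, 20, 20), 0.37)
    out = apply_channel(kernel, rates, (20, 20), clip=False)
    centre = out[:, 8:12, 8:12]
    assert np.allclose(centre, 0.37, atol=1e-9)


def test_channel_output_is_clipped_to_unit_interval():
    rng = np.random.default_rng(2)
    kernel = K.Kernel(
        spatial=rng.standard_normal((2, 7, 7)) * 3,
        feature=rng.random((2, 2)),
        channel_type="FF",
    )
    out = apply_channel(kernel, rng.random((2, 16, 16)), (8, 8))
    assert out.min() >= 0.0 and out.max() <= 1.0


def test_fb_channel_combines_pathways_with_xi():
    kpos, kneg = K.make_fb_kernels(1.0, 4)
    rng = np.random.default_rng(3)
    rates = rng.random((4, 12, 12))
    g0 = apply_fb_channel(kpos, kneg, 0.0, rates, (12, 12))
    gp = apply_channel(kpos, rates, (12, 12))
    assert np.allclose(g0, gp)  # xi=0 leaves the pure excitatory pathway
    gneg = apply_fb_channel(kpos, kneg, -1.0, rates, (12, 12))
    assert np.all(gneg <= g0 + 1e-12)


def test_collinear_feedback_is_excitatory_orthogonal_suppressive():
    """A like-oriented collinear source excites; an orthogonal-only source
    contributes suppression at on-axis positions (pre-rectification)."""
    n = 8
    kpos, kneg = K.make_fb_kernels(1.5, n)
    horizontal = n // 2  # theta = pi/2 in this indexing is vertical; use 0
    rates = np.zeros((n, 21, 21))
    rates[0, 10, :] = 1.0  # horizontal line in the horizontal channel
    g = apply_fb_channel(kpos, kneg, -1.0, rates, (21, 21))
    assert g[0, 10, 10] > 0  # collinear, like-oriented: net excitatory
    rates_orth = np.zeros((n, 21, 21))
    rates_orth[horizontal, 10, :] = 1.0  # same geometry, orthogonal tuning
    g2 = apply_fb_channel(kpos, kneg, -1.0, rates_orth, (21, 21))
    assert g2[0, 10, 10] < g[0, 10, 10]
    assert g2[0, 10, 10] <= 0  # orthogonal-only context suppresses


def test_network_structure_matches_connectivity_table():
    net = build_network(ct.default_params(), (64, 64))
    keys = {(c.channel_type, c.source, c.target) for c in net.channels}
    assert len(net.channels) == 15
    assert keys == {(c, s, t) for s, t, c in CONNECTIVITY}
    # no feedback into V4; HO accumulates from V1, V2, V4 and the task module
    assert not any(c.channel_type == "FB" and c.target == "V4" for c in net.channels)
    b1_sources = {c.source for c in net.channels if c.channel_type == "B1"}
    assert b1_sources == {"V1", "V2", "V4", "S"}


def test_scale_space_shapes():
    net = build_network(ct.default_params(), (140, 280))
    shapes = {a.name: a.shape for a in net.areas.values()}
    assert shapes["V1"] == (140, 280)
    assert shapes["V2"] == (70, 140)
    assert shapes["V4"] == (35, 70)
    assert shapes["HO"] == (92, 185)  # round-half-up of 0.66 x input
    assert net.areas["HO"].n_features == 1


def test_lesion_disables_named_channels_only():
    net = build_network(ct.default_params(), (64, 64))
    les = lesion(net, LesionSpec.parse(["FB:V4:V2", "B1:V2:HO"]))
    assert not les.channel("FB", "V4", "V2").enabled
    assert not les.channel("B1", "V2", "HO").enabled
    n_disabled = sum(not c.enabled for c in les.channels)
    assert n_disabled == 2
    # original untouched; empty spec is the identity
    assert all(c.enabled for c in net.channels)
    same = lesion(net, LesionSpec())
    assert all(c.enabled for c in same.channels)


def test_unknown_lesion_triple_is_rejected():
    with pytest.raises(ValueError):
        LesionSpec.parse(["FF:V4:V1"])


def test_resize_round_trip_of_smooth_field_is_bounded():
    yy, xx = np.mgrid[0:64, 0:64]
    field = 0.5 + 0.4 * np.sin(xx / 9.0) * np.cos(yy / 11.0)
    down = resize_field(field, (32, 32))
    back = resize_field(down, (64, 64))
    assert np.max(np.abs(back - field)) < 0.05
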