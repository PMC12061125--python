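import numpy as np
import pytest

from cortrace import stimuli


GENERATORS = {
    "parallel_lines": lambda: stimuli.make_parallel_lines(
        length_px=60, distance_px=15, image_shape=(72, 100), margin=6.0
    ),
    "narrow_wide_pair": lambda: stimuli.make_narrow_wide_pair(
        0.4, wide_dist=30, narrow_dist=12, image_shape=(90, 160),
        length_px=120, transition_px=24, margin=6.0
    ),
    "crossing": lambda: stimuli.make_crossing(90.0, image_shape=(100, 100), length_px=60),
    "rings": lambda: stimuli.make_rings([20, 35], arc_deg=240.0),
    "spiral": lambda: stimuli.make_spiral(spacing_px=12, start_radius=5, turns=1.0),
    "pathfinder_like": lambda: stimuli.make_pathfinder_like(
        3, rng_seed=7, image_shape=(140, 140)
    ),
}


@pytest.mark.parametrize("name", sorted(GENERATORS))
def test_generators_are_bit_exact_reproducible(name):
    a, b = GENERATORS[name](), GENERATORS[name]()
    assert np.array_equal(a.image, b.image)
    assert a.target_path == b.target_path
    assert a.seeds == b.seeds


@pytest.mark.parametrize("name", sorted(GENERATORS))
def test_annotations_are_consistent(name):
    stim = GENERATORS[name]()
    h, w = stim.image.shape
    path = np.asarray(stim.target_path)
    # inside bounds, label per position
    assert path[:, 0].min() >= 0 and path[:, 0].max() < h
    assert path[:, 1].min() >= 0 and path[:, 1].max() < w
    assert len(stim.segment_labels) == len(stim.target_path)
    # 8-connected and non-repeating
    steps = np.abs(np.diff(path, axis=0)).max(axis=1)
    assert np.all(steps == 1)
    # luminance support along the path (dashed stimuli are lit only on dashes)
    lum = stim.image[path[:, 0], path[:, 1]]
    if stim.meta.get("dashed"):
        assert np.mean(lum > 0) > 0.4
    else:
        assert np.all(lum > 0)
    # seeds lie inside the image
    for _, (r, c) in stim.seeds:
        assert 0 <= r < h and 0 <= c < w
    assert np.all(stim.image >= 0) and np.all(stim.image <= 1)


def test_parallel_lines_spacing_matches_request():
    stim = stimuli.make_parallel_lines(
        length_px=60, distance_px=15, image_shape=(72, 100), margin=6.0
    )
    tgt = np.asarray(stim.target_path, dtype=float)
    dis = np.asarray(stim.distractor_paths[0], dtype=float)
    from scipy.spatial import cKDTree

    dmin = cKDTree(dis).query(tgt)[0]
    assert abs(dmin.min() - 15) <= 1  # rasterization tolerance


def test_narrow_wide_labels_cover_requested_fraction():
    stim = stimuli.make_narrow_wide_pair(
        0.5, wide_dist=30, narrow_dist=12, image_shape=(90, 200),
        length_px=160, transition_px=20, margin=6.0
    )
    labels = np.asarray(stim.segment_labels)
    frac = np.mean(labels == "narrow")
    # transition halves fall on either side of the cut, so half +- taper
    assert abs(frac - 0.5) <= 20 / 160
    assert list(dict.fromkeys(stim.segment_labels)) == ["wide1", "narrow", "wide2"]


def test_narrow_fraction_zero_gives_uniform_wide_pair():
    stim = stimuli.make_narrow_wide_pair(
        0.0, wide_dist=30, narrow_dist=12, image_shape=(90, 160),
        length_px=120, margin=6.0
    )
    tgt = np.asarray(stim.target_path, dtype=float)
    dis = np.asarray(stim.distractor_paths[0], dtype=float)
    assert set(stim.segment_labels) == {"wide1"}
    # constant separation
    assert np.allclose(np.unique(dis[:, 0]), np.unique(tgt[:, 0]) + 30)


def test_crossing_seed_swap_mirrors_annotation():
    a = stimuli.make_crossing(90.0, image_shape=(100, 100), length_px=60, target="A")
    b = stimuli.make_crossing(90.0, image_shape=(100, 100), length_px=60, target="B")
    assert np.array_equal(a.image, b.image)
    assert a.target_path == b.distractor_paths[0]
    assert b.target_path == a.distractor_paths[0]
    assert a.seeds == b.seeds


def test_ring_arc_length_scales_with_radius():
    small = stimuli.make_rings([30], arc_deg=240.0)
    big = stimuli.make_rings([60], arc_deg=240.0)
    ratio = len(big.target_path) / len(small.target_path)
    assert abs(ratio - 2.0) < 0.1


def test_spiral_interarm_spacing_matches_request():
    stim = stimuli.make_spiral(spacing_px=15, start_radius=6, turns=1.5)
    from scipy.spatial import cKDTree

    tgt = np.asarray(stim.target_path, dtype=float)
    dis = np.asarray(stim.distractor_paths[0], dtype=float)
    # measure away from the arm ends where the distractor arm has ended
    interior = tgt[len(tgt) // 4 : -len(tgt) // 4]
    d = cKDTree(dis).query(interior)[0]
    assert np.median(d) == pytest.approx(15, abs=2)


def test_pathfinder_distractor_free_field_contains_single_curve():
    stim = stimuli.make_pathfinder_like(0, rng_seed=3, image_shape=(140, 140))
    assert stim.distractor_paths == []
    from skimage.measure import label

    n_components = label(stim.image > 0.2, connectivity=2).max()
    # every component is one dash of the single target curve: arc length
    # over the dash period (8 on, 6 off), with rasterization slack and the
    # seed dot possibly merging with the first dash
    arc = np.abs(np.diff(np.asarray(stim.target_path), axis=0)).max(axis=1).sum()
    expected = arc / (8 + 6)
    assert 0.7 * expected - 2 <= n_components <= 1.5 * expected + 2


def test_save_load_round_trip(tmp_path):
    stim = stimuli.make_parallel_lines(
        length_px=60, distance_px=15, image_shape=(72, 100), margin=6.0
    )
    stim.save(tmp_path / "stim")
    loaded = stimuli.Stimulus.load(tmp_path / "stim")
    assert np.allclose(loaded.image, stim.image, atol=1 / 255)
    assert loaded.target_path == stim.target_path
    assert loaded.segment_labels == stim.segment_labels


@pytest.mark.parametrize(
    "factory",
    [
        lambda: stimuli.make_parallel_lines(length_px=0, distance_px=15),
        lambda: stimuli.make_parallel_lines(length_px=60, distance_px=0),
        lambda: stimuli.make_narrow_wide_pair(1.5),
        lambda: stimuli.make_narrow_wide_pair(0.3, wide_dist=15, narrow_dist=20),
        lambda: stimuli.make_crossing(0.0),
        lambda: stimuli.make_crossing(90.0, image_shape=(40, 40), length_px=200),
        lambda: stimuli.make_rings([30, 20]),
        lambda: stimuli.make_rings([30], arc_deg=0.0),
        lambda: stimuli.make_spiral(turns=0.0),
    ],
)
def test_invalid_geometry_raises(factory):
    with pytest.raises(ValueError):
        factory()
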