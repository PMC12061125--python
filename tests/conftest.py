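import pytest

import cortrace as ct


@pytest.fixture(scope="session")
def small_params():
    """A small-network parameterization used by fast unit tests."""
    return ct.default_params().override({"n_theta": 2})


@pytest.fixture(scope="session")
def tiny_line_stimulus():
    """A short line pair in a small image, traceable in a few dozen sweeps."""
    return ct.make_parallel_lines(
        length_px=60, distance_px=20, image_shape=(72, 100), margin=6.0
    )


@pytest.fixture(scope="session")
def tiny_trace(tiny_line_stimulus):
    net = ct.build_network(ct.default_params(), tiny_line_stimulus.image.shape)
    return ct.run(net, tiny_line_stimulus, n_steps=150, record_every=50)
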