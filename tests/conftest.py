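import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_blocky_mask(rng, size=64, n_blocks=4):
    """Random union of solid rectangles: a generic binary shape for thinning."""
    m = np.zeros((size, size), dtype=bool)
    for _ in range(n_blocks):
        r, c = rng.integers(5, size - 14, 2)
        h, w = rng.integers(3, 12, 2)
        m[r : r + h, c : c + w] = True
    return m


def random_walk_polyline(rng, n=60, step=8.0):
    """Smooth-ish random polyline for simplification tests."""
    angles = np.cumsum(rng.normal(0, 0.4, n))
    steps = np.stack([np.cos(angles), np.sin(angles)], axis=1) * step
    return np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)]) + 100.0
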