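import numpy as np
import pytest
from hypothesis import settings

from affectpath.types import EmotionGraph, GraphVertex, Quadrant

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_graph():
    """Two vertices joined in a 2-cycle with known weights."""
    g = EmotionGraph()
    a = GraphVertex(0, Quadrant.I)
    b = GraphVertex(1, Quadrant.II)
    g.add_edge(a, b, 1.3)
    g.add_edge(b, a, 0.7)
    return g, a, b


@pytest.fixture
def three_blobs(rng):
    """600 points in three 200-point Gaussian blobs (sigma 100 m) with
    centers at least 5 km apart; returns (points, true labels)."""
    centers = np.array([[121.30, 31.00], [121.35, 31.00], [121.30, 31.05]])
    pts, truth = [], []
    for k, c in enumerate(centers):
        pts.append(c + rng.normal(0, 100, size=(200, 2)) / 111_320.0)
        truth += [k] * 200
    return np.vstack(pts), np.array(truth)
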