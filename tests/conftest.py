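import numpy as np
import pytest

from leafmorph.contour import Contour
from leafmorph.synthetic import LeafParams, generate_leaf


@pytest.fixture(scope="session")
def default_leaf():
    """Default toothed leaf with petiole (3 teeth per side, no noise)."""
    return generate_leaf(LeafParams(n_teeth=3, seed=0))


@pytest.fixture(scope="session")
def smooth_leaf():
    """Tooth-free leaf with petiole."""
    return generate_leaf(LeafParams(n_teeth=0, seed=0))


@pytest.fixture(scope="session")
def convex_leaf():
    """Tooth-free petiole-less (fully convex) leaf."""
    return generate_leaf(LeafParams(n_teeth=0, petiole=False, seed=0))


@pytest.fixture
def circle_contour():
    theta = np.linspace(0, 2 * np.pi, 1024, endpoint=False)
    return Contour(np.column_stack([2.0 * np.cos(theta), 2.0 * np.sin(theta)]))


@pytest.fixture
def unit_square():
    return Contour(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


def random_simple_polygon(rng: np.random.Generator, n: int = 12) -> Contour:
    """Star-shaped (hence simple) random polygon around the origin."""
    theta = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = rng.uniform(0.5, 2.0, n)
    return Contour(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
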