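import numpy as np
import pytest

from medusim.geometry import TankGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cavity():
    """1 m x 1 m stationary-wall tank, 21 x 21 nodes."""
    return TankGeometry(0.0, 1.0, 0.0, 1.0, 21, 21, "cavity")


@pytest.fixture
def hex_lattice():
    """Perfect hexagonal lattice positions and an interior-agent mask."""
    a = 1.0
    rows, cols = 12, 12
    pts = []
    for r in range(rows):
        for c in range(cols):
            pts.append((c * a + (r % 2) * a / 2, r * a * np.sqrt(3) / 2))
    pts = np.asarray(pts)
    x, y = pts[:, 0], pts[:, 1]
    interior = (
        (x > 1.5 * a) & (x < x.max() - 1.5 * a) & (y > 1.5 * a) & (y < y.max() - 1.5 * a)
    )
    return x, y, interior
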