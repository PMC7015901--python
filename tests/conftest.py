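import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seedmorph import CellPolygon

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def unit_square():
    return CellPolygon("s0", "l0", "sq", [(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def abutting_squares():
    """Ten 1x1 µm squares abutting along the x-axis."""
    return [
        CellPolygon("s0", "l0", f"c{i}", [(i, 0), (i + 1, 0), (i + 1, 1), (i, 1)])
        for i in range(10)
    ]


def star_polygon(rng, n_vertices=None, r_min=2.0, r_max=4.0, center=(0.0, 0.0)):
    """Random star-shaped (hence simple) polygon around a centre.

    Simplicity requires every angular gap between consecutive vertices
    (including the wrap-around) to stay below pi, else the closing chord
    can cross other edges.
    """
    n = n_vertices or int(rng.integers(5, 12))
    while True:
        angles = np.sort(rng.uniform(0, 2 * np.pi, n))
        gaps = np.diff(np.concatenate([angles, [angles[0] + 2 * np.pi]]))
        if np.all(gaps > 1e-3) and np.all(gaps < 3.0):
            break
    radii = rng.uniform(r_min, r_max, n)
    pts = np.column_stack(
        [center[0] + radii * np.cos(angles), center[1] + radii * np.sin(angles)]
    )
    return pts


def rotation(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def rectangle_cell(a, b, theta=0.0, center=(0.0, 0.0), cell_id="r"):
    """An a (anticlinal) x b (periclinal) rectangle rotated by theta."""
    base = np.array(
        [[-b / 2, -a / 2], [b / 2, -a / 2], [b / 2, a / 2], [-b / 2, a / 2]]
    )
    verts = base @ rotation(theta).T + np.asarray(center)
    return CellPolygon("s0", "l0", cell_id, verts)
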