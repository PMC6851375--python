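"""Shared fixtures: analytic paths, synthetic subjects, small meshes."""

import numpy as np
import pytest

from locodist import (
    Arena,
    SmoothingParams,
    TriMesh,
    analytic_trajectory,
    simulate_trajectory,
)
from locodist.synthetic import CRUISE, ERRATIC

#: smoothing used for synthetic-cohort analyses: a 1-second window at 20 fps,
#: matched to the simulator's kinematic time scale (darting and freezing
#: transitions last a few hundred ms and would be flattened by much longer
#: windows).
SYNTH_SMOOTHING = SmoothingParams(3, 21)


@pytest.fixture(scope="session")
def arena():
    return Arena(200.0, 120.0)


@pytest.fixture(scope="session")
def circle_traj():
    """R = 50 mm circle at omega = 1 rad/s, fps = 100: speed 50, curvature 0.02."""
    return analytic_trajectory("circle", duration_s=6.0, fps=100.0, radius=50.0, omega=1.0)


@pytest.fixture(scope="session")
def line_traj():
    return analytic_trajectory("line", duration_s=1.8, fps=100.0, speed=100.0)


@pytest.fixture(scope="session")
def cruise_traj():
    return simulate_trajectory(CRUISE, 120.0, 20.0, seed=101, subject_id="cruise-A")


@pytest.fixture(scope="session")
def erratic_traj():
    return simulate_trajectory(ERRATIC, 120.0, 20.0, seed=202, subject_id="erratic-A")


@pytest.fixture(scope="session")
def hex_wheel_mesh():
    """Flat hexagonal wheel: one interior vertex, six boundary vertices."""
    ang = np.linspace(0.0, 2.0 * np.pi, 7)[:-1]
    pts = np.vstack([[0.0, 0.0], np.column_stack([np.cos(ang), np.sin(ang)])])
    tris = np.array([(0, 1 + i, 1 + (i + 1) % 6) for i in range(6)])
    return TriMesh(np.column_stack([pts, np.zeros(7)]), tris)


@pytest.fixture(scope="session")
def square_pair_meshes():
    """Unit square split by one diagonal, and its uniform 2x scaling."""
    v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    t = np.array([[0, 1, 2], [0, 2, 3]])
    return TriMesh(v, t), TriMesh(2.0 * v, t)


def smooth_random_heatmap(rng, arena, grid=(10, 6), n_bumps=3):
    """Random smooth occupancy field: a few Gaussian bumps over a floor."""
    m, n = grid
    xs = (np.arange(m) + 0.5) / m
    ys = (np.arange(n) + 0.5) / n
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    rho = np.full((m, n), 0.2)
    for _ in range(n_bumps):
        cx, cy = rng.uniform(0.2, 0.8, 2)
        s = rng.uniform(0.15, 0.3)
        rho += rng.uniform(0.5, 1.5) * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * s * s))
    from locodist import HeatMap

    return HeatMap(rho / rho.sum(), arena)
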