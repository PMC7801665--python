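"""Shared fixtures: synthetic sessions with known ground truth."""
import numpy as np
import pytest

from gridnet import synthetic
from gridnet.types import GroundTruth


@pytest.fixture(scope="session")
def traj20():
    """20-minute foraging trajectory in the 1 m arena at 50 Hz."""
    return synthetic.generate_trajectory(1200.0, arena_size=1.0, fs=50.0,
                                         mean_speed=0.15, seed=7)


@pytest.fixture(scope="session")
def grid_gt():
    return GroundTruth(cell_type="grid", spacing=0.4, orientation=0.3,
                       phase=(0.13, 0.07), peak_rate=15.0, baseline_rate=0.3)


@pytest.fixture(scope="session")
def grid_cell(traj20, grid_gt):
    """A well-tuned grid cell sampled over the 20-minute session."""
    return synthetic.generate_grid_spikes(traj20, grid_gt, seed=11)


@pytest.fixture(scope="session")
def traj5():
    """5-minute trajectory for cheaper tests."""
    return synthetic.generate_trajectory(300.0, seed=3)


def hex_bump_lattice(n=60, spacing=12.0, sigma=2.5, orient=0.0, phase=(0.0, 0.0)):
    """Ideal hexagonal lattice of Gaussian bumps (constructed oracle map)."""
    a1 = spacing * np.array([np.cos(orient), np.sin(orient)])
    a2 = spacing * np.array([np.cos(orient + np.pi / 3),
                             np.sin(orient + np.pi / 3)])
    img = np.zeros((n, n))
    X, Y = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    for i in range(-10, 11):
        for j in range(-10, 11):
            cx = n / 2 + i * a1[0] + j * a2[0] + phase[0]
            cy = n / 2 + i * a1[1] + j * a2[1] + phase[1]
            if -4 * sigma < cx < n + 4 * sigma and -4 * sigma < cy < n + 4 * sigma:
                img += np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * sigma ** 2))
    return img
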