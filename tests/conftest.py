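"""Shared fixtures: a reduced-scale arena and pre-rendered recordings.

The study-scale recording (1920 x 1080 px, 300 frames) is too heavy to
re-render for every test, so most image-based tests run on a quarter-size
field of view at the same pixel scale and pillar geometry; nothing about
the measurement chain changes with the crop.
"""

from __future__ import annotations

import numpy as np
import pytest

from nemaflex import simulate as sim
from nemaflex.geometry import DeviceGeometry
from nemaflex.grid import make_pillar_grid


@pytest.fixture(scope="session")
def geometry() -> DeviceGeometry:
    """Reduced field of view, otherwise the default device."""
    return DeviceGeometry(image_width_px=640, image_height_px=480)


@pytest.fixture(scope="session")
def full_geometry() -> DeviceGeometry:
    return DeviceGeometry()


@pytest.fixture(scope="session")
def worm() -> sim.WormModel:
    return sim.WormModel(length_um=1077.0, diameter_um=45.0)


@pytest.fixture(scope="session")
def recording(geometry, worm):
    """One 24 s noisy recording with ground truth (rendered once)."""
    stack, gt, grid, centerlines = sim.generate_recording(
        worm, geometry, duration_s=24.0, noise_sd=5.0, seed=11
    )
    return {
        "stack": stack,
        "ground_truth": gt,
        "grid": grid,
        "centerlines": centerlines,
        "worm": worm,
    }


@pytest.fixture(scope="session")
def noiseless_recording(geometry, worm):
    """Same scene rendered without camera noise (seed-matched forces)."""
    stack, gt, grid, centerlines = sim.generate_recording(
        worm, geometry, duration_s=10.0, noise_sd=0.0, seed=21
    )
    return {
        "stack": stack,
        "ground_truth": gt,
        "grid": grid,
        "centerlines": centerlines,
        "worm": worm,
    }


@pytest.fixture(scope="session")
def worm_free_stack(geometry):
    """Noisy recording of the bare arena (no worm, no forces)."""
    grid = make_pillar_grid(geometry)
    n_frames = 60
    gt = sim.GroundTruth(
        contacts=[
            (np.empty(0, dtype=int), np.empty((0, 2)), np.empty((0, 2)))
            for _ in range(n_frames)
        ],
        frame_max_force_uN=np.zeros(n_frames),
        frame_max_pillar=np.full(n_frames, -1, dtype=int),
        true_f95_uN=0.0,
        seed=0,
    )
    stack = sim.render_frames(
        np.empty((0, 0, 2)), grid, gt, geometry, worm=None, noise_sd=5.0, seed=5
    )
    return {"stack": stack, "grid": grid}
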