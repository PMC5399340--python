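"""Shared fixtures: analytic translatable images and small speckle sequences."""

from __future__ import annotations

import numpy as np
import pytest

from tendontrack import (
    MotionProfile,
    PhantomSpec,
    Region,
    TrackerConfig,
    render_sequence,
)


def smooth_image(shape: tuple[int, int], shift_x: float = 0.0) -> np.ndarray:
    """Band-limited analytic texture, exactly translatable by any sub-pixel
    amount (the shifted image is the same function sampled at x - s)."""
    h, w = shape
    y, x = np.mgrid[0:h, 0:w].astype(float)
    xx = x - shift_x
    return (
        0.5
        + 0.2 * np.sin(2 * np.pi * xx / 23.0)
        + 0.15 * np.sin(2 * np.pi * y / 17.0)
        + 0.1 * np.sin(2 * np.pi * (xx + y) / 13.0)
        + 0.001 * xx
    )


@pytest.fixture(scope="session")
def default_config() -> TrackerConfig:
    return TrackerConfig()


@pytest.fixture(scope="session")
def speckle_frame() -> np.ndarray:
    """One static speckle frame, 150 x 300 px."""
    spec = PhantomSpec(
        motion=MotionProfile.constant_velocity(2, 0.0),
        width=300,
        height=150,
        seed=7,
    )
    seq, _ = render_sequence(spec)
    return seq[0]


@pytest.fixture(scope="session")
def shifted_speckle_pair():
    """Factory: noise-free speckle frame pair with a known global shift."""

    def make(dx: float, dy: float = 0.0, seed: int = 3, size=(300, 150)):
        w, h = size
        spec = PhantomSpec(
            motion=MotionProfile(np.array([[0.0, 0.0], [dx, dy]])),
            width=w,
            height=h,
            seed=seed,
        )
        seq, _ = render_sequence(spec)
        return seq[0], seq[1]

    return make


@pytest.fixture(scope="session")
def centered_region() -> Region:
    """Default 101x41 region placed centrally in a 150x300 frame."""
    return Region(80, 50, 101, 41)
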