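import numpy as np
import pytest

from thermofoot.calibration import Correspondences, KeypointSet, from_point_arrays
from thermofoot.synthgen import (
    DEFAULT_RIG,
    RigConfig,
    make_checkerboard_scene,
    make_foot_mask,
    make_scene_bundle,
)
from thermofoot.transforms import CameraModel, Transform2D, apply_to_points


@pytest.fixture(scope="session")
def rig() -> RigConfig:
    return DEFAULT_RIG


@pytest.fixture(scope="session")
def quiet_rig(rig) -> RigConfig:
    """The default rig with all image noise switched off."""
    import dataclasses

    return dataclasses.replace(rig, image_noise_sigma=0.0)


@pytest.fixture(scope="session")
def focal_bundle(rig):
    return make_scene_bundle(rig, rig.focal_plane_mm, seed=100)


@pytest.fixture(scope="session")
def foot_mask():
    return make_foot_mask(384, 288, seed=3)


def make_h_correspondences(
    h: np.ndarray,
    n_inliers: int,
    n_outliers: int,
    jitter_px: float,
    seed: int,
    extent: float = 300.0,
) -> tuple[Correspondences, np.ndarray]:
    """Correspondences of a known homography plus gross mismatches.

    Returns the correspondence set and the boolean inlier labels.  Outlier
    destinations are displaced by 10-60 px so they cannot sit inside a
    couple of pixels of the true model.
    """
    rng = np.random.default_rng(seed)
    # jittered grid keeps every point pair well separated
    n = n_inliers + n_outliers
    side = int(np.ceil(np.sqrt(n)))
    step = extent / side
    grid = np.array(
        [(20 + step * j, 20 + step * i) for i in range(side) for j in range(side)]
    )
    src = grid[rng.permutation(len(grid))[:n]] + rng.uniform(-step / 8, step / 8, (n, 2))
    t = Transform2D(h, "homography")
    dst = apply_to_points(t, src)
    if jitter_px > 0:
        dst = dst + rng.normal(0, jitter_px, dst.shape)
    labels = np.zeros(len(src), bool)
    labels[:n_inliers] = True
    true_dst = dst.copy()
    for i in range(n_inliers, len(src)):
        while True:
            angle = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(10, 60)
            moved = np.clip(
                true_dst[i] + [r * np.cos(angle), r * np.sin(angle)], 5.0, 1900.0
            )
            if np.linalg.norm(moved - true_dst[i]) >= 8.0:  # genuinely off-model
                dst[i] = moved
                break
    shape = (2000, 2000)
    return from_point_arrays(src, dst, shape, shape), labels
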