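import numpy as np
import pytest

from smglab import ImageGenConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cfg() -> ImageGenConfig:
    """Small but fully structured generator configuration for fast tests."""
    return ImageGenConfig(frame_height=40, frame_width=56, frame_rate=10, seed=12)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)


def random_cloud(rng, n_classes=3, n_reps=2, pts_per_rep=8, ndim=5,
                 spread=2.0):
    """Random labeled 5-D point cloud: per-class centers, per-rep sub-clusters."""
    points, classes, reps = [], [], []
    for c in range(n_classes):
        center = spread * rng.standard_normal(ndim)
        for r in range(1, n_reps + 1):
            sub = center + 0.5 * rng.standard_normal(ndim)
            pts = sub + rng.standard_normal((pts_per_rep, ndim))
            points.append(pts)
            classes += [f"c{c}"] * pts_per_rep
            reps += [r] * pts_per_rep
    return np.vstack(points), np.array(classes), np.array(reps)
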