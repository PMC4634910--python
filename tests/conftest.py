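import numpy as np
import pytest
from hypothesis import settings

import cinedense as cd

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_cfg() -> cd.PhantomConfig:
    """Reduced grid/frame count for fast unit tests."""
    return cd.PhantomConfig(grid_size=64, n_frames=24, es_frame=16)


@pytest.fixture(scope="session")
def small_truth(small_cfg) -> cd.PhantomTruth:
    return cd.build_phantom(small_cfg)


@pytest.fixture(scope="session")
def small_seg(small_truth) -> cd.Segmentation:
    return cd.segmentation_from_truth(small_truth)


@pytest.fixture(scope="session")
def default_truth() -> cd.PhantomTruth:
    """Full-scale (128 x 128, 30-frame) phantom at the study geometry."""
    return cd.build_phantom(cd.PhantomConfig())


@pytest.fixture(scope="session")
def default_seg(default_truth) -> cd.Segmentation:
    return cd.segmentation_from_truth(default_truth)


@pytest.fixture(scope="session")
def noisefree_series_small(small_truth) -> cd.DenseSeries:
    return cd.encode(
        small_truth, cd.EncodingConfig(ke_cycles_per_mm=0.10, target_snr=None)
    )


def analytic_trajectories(truth: cd.PhantomTruth):
    """TrajectorySet built directly from the phantom's closed-form positions."""
    from cinedense.mechanics import TrajectorySet

    return TrajectorySet(
        material_points=truth.material_coords.copy(),
        positions=truth.trajectories.copy(),
        valid=np.ones(truth.material_coords.shape[0], dtype=bool),
    )
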