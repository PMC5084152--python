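import numpy as np
import pytest

from mitotrack.core import AcquisitionMetadata
from mitotrack.simulate import ImagingParams, MotionModelParams, generate_dataset


@pytest.fixture
def metadata_small():
    """Small calibrated grid used across tests: 0.2 um px, 0.5 um z, 1.5 s."""
    return AcquisitionMetadata(
        pixel_size_xy=0.2,
        z_step=0.5,
        frame_interval=1.5,
        n_frames=20,
        n_z=5,
        height=64,
        width=128,
    )


@pytest.fixture
def noiseless_imaging():
    return ImagingParams(noise_model="none")


@pytest.fixture(scope="session")
def small_dataset():
    """A 5-particle, 20-frame noisy stack plus ground truth (fixed seed)."""
    md = AcquisitionMetadata(
        pixel_size_xy=0.2, z_step=0.5, frame_interval=1.5,
        n_frames=20, n_z=5, height=64, width=128,
    )
    seq, truth = generate_dataset(
        5, 20, MotionModelParams(), ImagingParams(), md, seed=1
    )
    return seq, truth


@pytest.fixture(scope="session")
def noiseless_dataset():
    """A 8-particle, 30-frame noiseless stack plus ground truth (fixed seed)."""
    md = AcquisitionMetadata(
        pixel_size_xy=0.2, z_step=0.5, frame_interval=1.5,
        n_frames=30, n_z=5, height=96, width=128,
    )
    seq, truth = generate_dataset(
        8, 30, MotionModelParams(), ImagingParams(noise_model="none"), md, seed=7
    )
    return seq, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
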