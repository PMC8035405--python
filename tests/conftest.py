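import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from osteomix.synthetic import SceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene_config():
    """A compact mosaic that still exercises stitching and tiling."""
    return SceneConfig(
        field_shape=(128, 128),
        field_grid=(2, 2),
        n_blue_cells=40,
        n_red_cells=11,
        r_blue_um=6.0,
        r_red_um=12.0,
        cluster_count=3,
        cluster_sd_um=20.0,
        snr=10.0,
        noise_sd=0.02,
        mixing_lambda=0.5,
        seed=42,
    )


@pytest.fixture
def small_volume_config():
    return SceneConfig(
        field_shape=(96, 96),
        field_grid=(1, 1),
        pixel_size_um=1.0,
        n_z=12,
        z_step_um=2.0,
        n_blue_cells=2,
        n_red_cells=1,
        r_blue_um=6.0,
        r_red_um=8.0,
        snr=10.0,
        noise_sd=0.01,
        seed=7,
    )
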