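import numpy as np
import pytest

from optopore import (
    SceneSpec,
    SegmentationParams,
    generate_fluorescence,
    learn_thresholds,
)


@pytest.fixture(scope="session")
def seg_params() -> SegmentationParams:
    return SegmentationParams()


@pytest.fixture(scope="session")
def control_scene():
    """Untreated control dish: all cells intact, default staining model."""
    spec = SceneSpec(
        image_height_px=1024,
        image_width_px=1024,
        n_cells=150,
        noise_sd=10.0,
        cell_radius_um=(5.0, 7.0),
        class_fractions=(1.0, 0.0, 0.0),
        seed=7,
    )
    dapi, etbr, calcein, truth = generate_fluorescence(spec)
    return spec, dapi, etbr, calcein, truth


@pytest.fixture(scope="session")
def control_thresholds(control_scene, seg_params):
    _, dapi, etbr, calcein, _ = control_scene
    return learn_thresholds(dapi, etbr, calcein, seg_params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
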