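import numpy as np
import pytest

from layerlens import (
    AffineLogitModel,
    LayerLabelMap,
    MultimodalScan,
    PhantomConfig,
    ScanMetadata,
    VolumeGrid,
    generate_cohort,
)


@pytest.fixture(scope="session")
def six_layer_labels() -> LayerLabelMap:
    """12-deep grid with six flat 2-voxel slabs, no background."""
    labels = np.zeros((12, 4, 4), dtype=np.int16)
    for code in range(1, 7):
        labels[(code - 1) * 2: code * 2] = code
    return LayerLabelMap(labels)


@pytest.fixture(scope="session")
def toy_scan(six_layer_labels) -> MultimodalScan:
    rng = np.random.default_rng(7)
    shape = six_layer_labels.shape
    bmode = VolumeGrid(rng.uniform(0.5, 1.5, shape), modality="bmode")
    swe = VolumeGrid(rng.uniform(1000, 9000, shape), modality="swe")
    return MultimodalScan("toy", [bmode, swe],
                          ScanMetadata(patient_id="p0", tender_points=1))


@pytest.fixture(scope="session")
def affine_model(toy_scan) -> AffineLogitModel:
    """Fixed affine-logit scorer over the toy scan's two channels."""
    rng = np.random.default_rng(11)
    w = rng.normal(0.0, 0.05, (2, *toy_scan.shape))
    return AffineLogitModel(w, bias=0.3)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small additive-signal phantom cohort for integration-style tests."""
    config = PhantomConfig(
        grid_shape=(16, 16, 16), n_patients=4, visits_per_patient=1,
        sites_per_side=1, bmode_reps=2, swe_reps=1, seed=5,
    )
    return generate_cohort(config)
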