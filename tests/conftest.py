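import numpy as np
import pytest

from dermafuse import (
    SyntheticFeatureSpec,
    SyntheticImageSpec,
    make_synthetic_features,
    make_synthetic_images,
)

#: the published per-class dermoscopy image counts of the seven-class set
HAM_COUNTS = {
    "NV": 6705,
    "MEL": 1113,
    "BKL": 1099,
    "BCC": 514,
    "AKIEC": 327,
    "VASC": 142,
    "DF": 115,
}


@pytest.fixture(scope="session")
def blob_features():
    """Well-separated 3-class blobs with known informative columns."""
    spec = SyntheticFeatureSpec(
        n_per_class=40, n_classes=3, d_informative=6, d_noise=14,
        separation=4.0, nonnegative=True, seed=11,
    )
    fm, labels, informative = make_synthetic_features(spec)
    return fm, labels, informative


@pytest.fixture(scope="session")
def small_images():
    """Seven balanced classes of 32x32 synthetic lesions."""
    return make_synthetic_images(
        SyntheticImageSpec(n_per_class=4, n_classes=7, height=32, width=32, seed=5)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
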