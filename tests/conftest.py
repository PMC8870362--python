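import numpy as np
import pytest

from tamgcs import GCSConfig, TrainConfig, gcs_cut_pipeline, make_labeled_imageset

OVERDEEP_ARCH = [
    dict(kind="conv2d", filters=8, kernel_size=3, activation="relu"),
    dict(kind="maxpool2d", pool=2),
    dict(kind="flatten"),
    dict(kind="dense", units=256, activation="relu"),
    dict(kind="dense", units=256, activation="relu"),
    dict(kind="dense", units=256, activation="relu"),
    dict(kind="dense", units=4, activation="softmax"),
]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def motif_imageset():
    """4-class 24x24 motif images: 150 train / 50 test per class."""
    return make_labeled_imageset(n_per_class=200, image_size=24, n_classes=4, seed=1)


@pytest.fixture(scope="session")
def cut_run(motif_imageset):
    """One full GCS-cut run on the over-deep network, shared across tests."""
    x_train, y_train, x_test, y_test = motif_imageset
    report, original, cut_model = gcs_cut_pipeline(
        x_train,
        y_train,
        x_test,
        y_test,
        OVERDEEP_ARCH,
        train_config=TrainConfig(epochs=20, seed=1),
        gcs_config=GCSConfig(seed=1),
        sample_cap=240,
        seed=1,
    )
    return report, original, cut_model
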