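import numpy as np
import pytest

from vasclite import models, phantom, pipeline


@pytest.fixture(scope="session")
def b0_original():
    return models.build_model("B0", "original", num_classes=2, seed=0)


@pytest.fixture(scope="session")
def b0_modified3():
    return models.build_model("B0", "modified3", num_classes=2, seed=0)


@pytest.fixture(scope="session")
def small_phantom_batch():
    """12 labeled 64x64 phantoms preprocessed to model tensors."""
    images, labels = phantom.generate_dataset(6, 6, seed=7, image_size=64)
    x = pipeline.preprocess_batch(images, 64)
    return x, np.asarray(labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_records(n_normal, n_abnormal, size=32, seed=0, split="train"):
    """Tiny labeled records without going through the phantom generator."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_normal + n_abnormal):
        label = 0 if i < n_normal else 1
        records.append(pipeline.ImageRecord(
            uid=f"img{i:04d}",
            image=rng.random((size, size), dtype=np.float32),
            label=label, split=split, source="fixture"))
    return records


@pytest.fixture()
def tiny_records():
    return make_records(4, 6)
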