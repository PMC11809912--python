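import numpy as np
import pytest

from crnsmote import ClassSpec, GeneratorSpec, LabeledDataset, make_imbalanced


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_imbalanced():
    """Two well-separated blobs, 10 vs 4 samples."""
    spec = GeneratorSpec(
        class_specs=(
            ClassSpec(label="p", count=10, centers=((0.2, 0.2),), spread=0.02),
            ClassSpec(label="q", count=4, centers=((0.8, 0.8),), spread=0.02),
        ),
        n_features=2,
        seed=7,
    )
    return make_imbalanced(spec)


@pytest.fixture
def two_blob_minority():
    """Minority class split into two separated blobs (exercises n_cluster=2)."""
    spec = GeneratorSpec(
        class_specs=(
            ClassSpec(label="maj", count=60, centers=((0.5, 0.9),), spread=0.02),
            ClassSpec(
                label="min", count=24, centers=((0.1, 0.1), (0.9, 0.1)), spread=0.02
            ),
        ),
        n_features=2,
        seed=11,
    )
    return make_imbalanced(spec)


@pytest.fixture
def noisy_imbalanced():
    """Moderately overlapping 2-class data with injected box noise."""
    spec = GeneratorSpec(
        class_specs=(
            ClassSpec(label="maj", count=120, centers=((0.35, 0.6),), spread=0.08),
            ClassSpec(label="min", count=50, centers=((0.65, 0.35),), spread=0.08),
        ),
        n_features=2,
        noise_fraction=0.08,
        seed=3,
    )
    return make_imbalanced(spec)


def random_dataset(rng, n=40, n_features=2, n_classes=2):
    """Unstructured random labeled data for oracle comparisons."""
    features = rng.random((n, n_features))
    labels = rng.integers(n_classes, size=n).astype(str)
    # ensure every class appears at least twice
    for c in range(n_classes):
        labels[2 * c] = str(c)
        labels[2 * c + 1] = str(c)
    return LabeledDataset(features=features, labels=labels)
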