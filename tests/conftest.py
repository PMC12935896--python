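import numpy as np
import pytest

from hrvbalance import HRVDataset, default_cohort_config, generate_cohort
from hrvbalance.datasets import FEATURE_NAMES


@pytest.fixture(scope="session")
def cohort():
    """Default 321-row synthetic cohort with the emulated class imbalance."""
    return generate_cohort(default_cohort_config(seed=11))


@pytest.fixture()
def two_cluster_ds():
    """Two tight, well-separated 10-point clusters, labels 1 and 2."""
    rng = np.random.default_rng(3)
    a = rng.normal(0.0, 0.1, size=(10, 9))
    b = rng.normal(20.0, 0.1, size=(10, 9))
    return HRVDataset(
        features=np.vstack([a, b]),
        labels=np.array([1] * 10 + [2] * 10),
        feature_names=FEATURE_NAMES,
    )


def make_dataset(features, labels, **kw):
    features = np.asarray(features, dtype=float)
    names = kw.pop("feature_names", tuple(f"f{i}" for i in range(features.shape[1])))
    return HRVDataset(features=features, labels=np.asarray(labels), feature_names=names, **kw)
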