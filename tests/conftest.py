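import numpy as np
import pytest
from hypothesis import settings

from localbalance.data_io import FeatureMatrix, LabeledDataset

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_ds(X, labels, sample_ids=None, feature_ids=None) -> LabeledDataset:
    """Build a LabeledDataset from plain arrays with synthesized ids."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    fm = FeatureMatrix(
        X,
        sample_ids or [f"s{i}" for i in range(n)],
        feature_ids or [f"f{j}" for j in range(p)],
    )
    return LabeledDataset(fm, np.asarray(labels, dtype=object))


@pytest.fixture
def separable_ds():
    """Two tight, well separated clusters: Low near the origin, Hi far away."""
    rng = np.random.default_rng(42)
    low = rng.normal(0.0, 0.1, (6, 3))
    hi = rng.normal(5.0, 0.1, (6, 3))
    return make_ds(np.vstack([low, hi]), ["Low"] * 6 + ["Hi"] * 6)
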