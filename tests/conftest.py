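import numpy as np
import pytest

from tierstack.data import FeatureMeta, RiskFactorDataset


@pytest.fixture
def tiny_meta():
    return [
        FeatureMeta("p1", "primary", "binary", 0),
        FeatureMeta("p2", "primary", "binary", 0),
        FeatureMeta("s1", "secondary", "binary", 0),
        FeatureMeta("s2", "secondary", "binary", 1),
    ]


@pytest.fixture
def tiny_dataset(tiny_meta):
    X = np.array(
        [
            [1, 0, 0, 1],
            [0, 1, 1, 0],
            [1, 1, 0, 0],
            [0, 0, 1, 1],
            [1, 0, 1, 0],
            [0, 1, 0, 1],
        ],
        dtype=float,
    )
    y = np.array([1, 0, 1, 0, 1, 0])
    return RiskFactorDataset(X=X, y=y, meta=tiny_meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
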