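import numpy as np
import pytest

from voxencode.data import EncodingDataset, FeatureBlock, ResponseBlock


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(
    rng,
    T_train=80,
    T_test=60,
    p=3,
    m=4,
    n_train=3,
    n_test=2,
    n_repeats=0,
    groups=None,
):
    """A small hand-rolled dataset with optional test repeats (pure noise)."""
    feats, resps = [], []
    for i in range(n_train):
        feats.append(FeatureBlock(rng.standard_normal((T_train, p)), f"tr{i}", "train"))
        resps.append(ResponseBlock(rng.standard_normal((T_train, m)), f"tr{i}"))
    for i in range(n_test):
        feats.append(FeatureBlock(rng.standard_normal((T_test, p)), f"te{i}", "test"))
        if n_repeats:
            reps = rng.standard_normal((n_repeats, T_test, m))
            resps.append(ResponseBlock(reps.mean(axis=0), f"te{i}", repeats=reps))
        else:
            resps.append(ResponseBlock(rng.standard_normal((T_test, m)), f"te{i}"))
    return EncodingDataset(feats, resps, list(groups or ["all"] * m))


@pytest.fixture
def small_dataset(rng):
    return make_dataset(rng)
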