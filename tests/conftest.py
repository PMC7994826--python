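import numpy as np
import pytest

from tftslstm.core import TimeSeries
from tftslstm.pipeline import FeatureSequence


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_cluster_points():
    """Two tight 1-d clusters at 0 and 10, 20 points each."""
    gen = np.random.default_rng(7)
    a = gen.normal(0.0, 0.1, size=20)
    b = gen.normal(10.0, 0.1, size=20)
    pts = np.concatenate([a, b])[:, None]
    labels = np.array([0] * 20 + [1] * 20)
    return pts, labels


def make_record(samples, fs=300.0, id="r", label=None):
    return TimeSeries(id=id, samples=np.asarray(samples, dtype=float), fs=fs, label=label)


@pytest.fixture
def separable_sequences():
    """Tiny linearly separable two-class feature sequences (M=5, Q=4)."""
    gen = np.random.default_rng(11)
    seqs = []
    for i in range(10):
        label = "pos" if i % 2 == 0 else "neg"
        shift = 2.0 if label == "pos" else -2.0
        feats = gen.normal(size=(5, 4)) * 0.3 + shift
        seqs.append(FeatureSequence(id=f"s{i}", features=feats, label=label))
    return seqs
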