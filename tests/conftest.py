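import numpy as np
import pytest

from reci.pair import Direction, ObservedPair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cluster_outlier_pair(rng):
    """200 tightly clustered points plus one far outlier (last position)."""
    x = np.concatenate([rng.normal(0.0, 0.05, 200), [5.0]])
    y = np.concatenate([rng.normal(0.0, 0.05, 200), [5.0]])
    return ObservedPair(x=x, y=y, name="cluster+outlier")


def make_pair(x, y, truth=Direction.NONE, **kw):
    return ObservedPair(x=np.asarray(x, float), y=np.asarray(y, float), truth=truth, **kw)
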