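import math

import numpy as np
import pytest

from hopfec.cohort import GroundTruth
from hopfec.datatypes import ConnectivityMatrix, HopfParameters, Parcellation


def brute_pearson(x, y):
    """Textbook sum-formula Pearson correlation (independent of numpy.corrcoef)."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def two_node_ground_truth(weight: float = 0.12, f: float = 0.04) -> GroundTruth:
    """Unidirectional 2-node generator: source node 0 drives target node 1."""
    v = np.zeros((2, 2))
    v[1, 0] = weight
    parc = Parcellation.bilateral(2)
    ec = ConnectivityMatrix(v, kind="EC", region_ids=list(parc.region_ids))
    params = HopfParameters(a=np.full(2, -0.02), f=np.array([f, f]))
    return GroundTruth(ec_true=ec, params=params, pairing=parc.homotopic_pairing(), parcellation=parc)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
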