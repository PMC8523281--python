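import numpy as np
import pytest

from gllsurv import GLLParams, bladder_cancer_remission_times
from gllsurv.fit import LifetimeSample


@pytest.fixture(scope="session")
def bladder() -> LifetimeSample:
    return bladder_cancer_remission_times()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


# a spread of valid parameter triples covering light and heavy tails
PARAM_GRID = [
    GLLParams(0.5, 0.5, 0.5),
    GLLParams(1.5, 0.5, 2.5),
    GLLParams(1.5, 1.0, 1.0),
    GLLParams(2.0, 1.0, 0.5),
    GLLParams(3.0, 2.0, 3.0),
    GLLParams(4.5, 4.0, 0.2),
    GLLParams(4.0, 5.0, 0.5),
    GLLParams(0.9, 0.5, 2.5),
]


@pytest.fixture(params=PARAM_GRID, ids=lambda p: f"a{p.alpha}-k{p.kappa}-e{p.eta}")
def params(request) -> GLLParams:
    return request.param


def random_params(rng: np.random.Generator, size: int = 1):
    """Log-uniform random valid triples, moderate range."""
    out = []
    for _ in range(size):
        a, k, e = np.exp(rng.uniform(np.log(0.3), np.log(5.0), 3))
        out.append(GLLParams(a, k, e))
    return out
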