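import numpy as np
import pytest

from latentcorr.model import FeatureData, FeatureParams, Hyperparams


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_feature(rng):
    """A small random feature with one zero-coverage cell."""
    I = 20
    y1 = rng.poisson(4.0, I)
    n = rng.integers(5, 50, I)
    n[3] = 0
    y2 = rng.binomial(n, 0.35)
    s = np.exp(rng.normal(0.0, 0.2, I))
    return FeatureData("toy", y1, y2, n, s)


@pytest.fixture()
def toy_params(rng, toy_feature):
    X = rng.normal(0.0, 1.0, (toy_feature.n_cells, 2))
    X[:, 0] += 1.5
    return FeatureParams(
        mu1=1.5, mu2=-0.3, sigma1=1.2, sigma2=0.8, rho=0.4, pi=0.15, X=X
    )


@pytest.fixture()
def hyper():
    return Hyperparams()
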