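import numpy as np
import pytest

import lomaxbayes as lb


@pytest.fixture(scope="session")
def reference_config():
    """The study design used throughout: sigma=3, (z,k)=(0.6,0.5), v=1, omega=0.5."""
    return lb.StudyConfig(seed=20210611)


@pytest.fixture(scope="session")
def study_result(reference_config):
    """One full 12-cell study at 10,000 replicates, shared across tests."""
    return lb.run_study(reference_config)


@pytest.fixture
def example_posterior():
    """Gamma(25.6, 25.5): the posterior for n=25, gamma=25 under the (0.6, 0.5) prior."""
    return lb.PosteriorGamma(25.6, 25.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def gauss_legendre_hyperprior_average(n, gamma, v, bayes_fn, order=40):
    """Independent 2-D quadrature oracle: average a Bayes estimator over
    z ~ U(0,1), k ~ U(0,v) with a Gauss-Legendre product rule."""
    x, w = np.polynomial.legendre.leggauss(order)
    z_nodes = 0.5 * (x + 1.0)
    z_weights = 0.5 * w
    k_nodes = 0.5 * v * (x + 1.0)
    k_weights = 0.5 * v * w
    total = 0.0
    for zi, wzi in zip(z_nodes, z_weights):
        post = lb.PosteriorGamma(n + zi, gamma + k_nodes)
        total += wzi * float(np.sum(k_weights * np.asarray(bayes_fn(post)))) / v
    return total
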