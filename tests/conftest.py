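import numpy as np
import pytest

import rpclust as rp


@pytest.fixture(scope="session")
def tiny_dataset():
    spec = rp.nhanes_like_spec("tiny", seed=7)
    data, truth = rp.generate_dataset(spec)
    return spec, data, truth


@pytest.fixture(scope="session")
def tiny_fit(tiny_dataset):
    """A short but converged chain on the tiny two-subgroup preset,
    shared across summary-level tests."""
    _, data, _ = tiny_dataset
    config = rp.MCMCConfig(n_iter=1200, k0_max=8, ks_max=8, burn_in=600,
                           thin=3, seed=21)
    return rp.run_mcmc(data, config)


def random_params(rng, K0, Ks, S, p, d):
    """Valid random model parameters for likelihood tests."""
    pi = rng.dirichlet(np.ones(K0))
    lam = rng.dirichlet(np.ones(Ks), size=S)
    theta0 = rng.dirichlet(np.ones(d), size=(K0, p))
    theta1 = rng.dirichlet(np.ones(d), size=(S, Ks, p))
    nu = rng.random((S, p))
    n = 1
    return rp.RPCParameters(
        pi=pi, lam=lam, theta0=theta0, theta1=theta1, nu=nu,
        z=np.zeros(n, dtype=int), c=np.zeros(n, dtype=int),
        G=np.ones((n, p), dtype=np.int8))
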