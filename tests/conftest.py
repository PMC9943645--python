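import numpy as np
import pytest

import stagecast as sc


@pytest.fixture(scope="session")
def small_truth():
    return sc.make_truth(3, effect_scale=0.3, seed=1)


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    rain = sc.make_rainfall(15, seed=2)
    topo = sc.grid_topology(10)
    data, latent = sc.simulate_community(small_truth, topo, 15, rain, seed=3)
    return data, latent


@pytest.fixture(scope="session")
def fitted(small_dataset):
    """One reduced-design fit shared by the inference/diagnostic tests."""
    data, _ = small_dataset
    cfg = sc.RunConfig(chains=2, warmup=2000, draws=1100, target_samples=2100)
    return sc.fit_model(data, cfg, seed=7)


def random_rateset(rng, k, p):
    return sc.RateSet(
        theta=rng.uniform(0.05, 0.95, (k, p)),
        phi=rng.uniform(0.05, 0.95, (k, p)),
        tau=rng.uniform(0.05, 0.9, k),
        gamma=rng.uniform(0.05, 0.9, k),
        rho=rng.uniform(0.1, 4.0, k),
    )


def random_dispersal(rng, p):
    """Random column-stochastic dispersal matrix."""
    D = rng.uniform(0.0, 1.0, (p, p)) * (rng.random((p, p)) < 0.4)
    np.fill_diagonal(D, rng.uniform(0.5, 1.0, p))
    return D / D.sum(axis=0, keepdims=True)
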