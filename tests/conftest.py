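import numpy as np
import pandas as pd
import pytest

from dietcnv import simulate, trees


def yule_tree(n_species: int, seed: int, birth_rate: float = 1.0):
    """Random pure-birth tree used across the suite."""
    params = simulate.SimParams(n_species=n_species, seed=seed,
                                birth_rate=birth_rate)
    return simulate.simulate_tree(params)


def bm_trait(cov: trees.PhyloCov, seed: int, sigma2: float = 1.0):
    """Brownian-motion trait draw on a given covariance."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(cov.C + 1e-12 * np.eye(len(cov.species)))
    return np.sqrt(sigma2) * (L @ rng.standard_normal(len(cov.species)))


@pytest.fixture
def three_tip_tree():
    return trees.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def hc_cloud():
    """Well-separated herbivore/carnivore Gaussian clouds (25 + 43)."""
    rng = np.random.default_rng(42)
    n_h, n_c, p = 25, 43, 6
    X = pd.DataFrame(
        np.vstack([rng.normal(3.0, 1.0, (n_h, p)),
                   rng.normal(0.0, 1.0, (n_c, p))]),
        columns=[f"fam{i}" for i in range(p)],
        index=[f"sp{i}" for i in range(n_h + n_c)],
    )
    labels = np.array(["herbivore"] * n_h + ["carnivore"] * n_c)
    return X, labels
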