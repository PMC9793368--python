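import numpy as np
import pytest

from cdikit.io import CountMatrix, LabelSet


def nb_rvs(rng, mu, phi, size=None):
    """NB draws under the mean/dispersion parametrization (phi=0 -> Poisson)."""
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.all(phi == 0):
        return rng.poisson(mu, size=size)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), size=size)


def make_counts(X, batch=None):
    X = np.asarray(X)
    return CountMatrix(
        X,
        [f"g{i + 1}" for i in range(X.shape[0])],
        [f"c{j + 1}" for j in range(X.shape[1])],
        batch,
    )


def make_clustered_counts(rng, mus, phis, cells_per_cluster):
    """Counts from per-(gene, cluster) NB parameters; returns (counts, labels).

    ``mus``/``phis`` are (G, K) arrays, ``cells_per_cluster`` a length-K list.
    """
    mus = np.asarray(mus, dtype=float)
    phis = np.asarray(phis, dtype=float)
    blocks, labs = [], []
    for k in range(mus.shape[1]):
        nk = cells_per_cluster[k]
        blocks.append(nb_rvs(rng, mus[:, [k]], phis[:, [k]], (mus.shape[0], nk)))
        labs.append(np.full(nk, k + 1))
    X = np.concatenate(blocks, axis=1)
    return make_counts(X), LabelSet(np.concatenate(labs))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
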