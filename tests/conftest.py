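import numpy as np
import pytest

from novatest import sim_data
from novatest.st_io import SpatialCountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_counts():
    """3 spots x 4 genes with coordinate-token spot ids."""
    counts = np.array(
        [
            [5, 0, 2, 1],
            [3, 1, 0, 1],
            [7, 2, 1, 0],
        ]
    )
    return SpatialCountMatrix(
        counts=counts,
        coords=np.array([[1.0, 1.0], [1.0, 2.0], [2.0, 1.0]]),
        gene_names=["GENE1", "ERCC-00096", "MT-CO1", "GENE2"],
        spot_ids=["1x1", "1x2", "2x1"],
    )


@pytest.fixture(scope="session")
def grid_coords_100():
    return sim_data.make_coords(sim_data.SimSpec(n_spots=100, grid="square", seed=0))


def dense_nll_oracle(y, coords, params, jitter_frac=1e-6):
    """Brute-force L1 via explicit inverse and determinant."""
    from scipy.spatial.distance import cdist

    d2 = cdist(coords, coords, "sqeuclidean")
    k = params.sigma_k2 * np.exp(-d2 / (2 * params.length_scale**2))
    kn = k + (jitter_frac * params.sigma_k2 + params.sigma_n2) * np.eye(len(y))
    resid = np.asarray(y, float) - params.mu_c
    inv = np.linalg.inv(kn)
    sign, logdet = np.linalg.slogdet(kn)
    assert sign > 0
    return 0.5 * resid @ inv @ resid + 0.5 * logdet + 0.5 * len(y) * np.log(2 * np.pi)


def dense_posterior_oracle(y, coords, params, query, jitter_frac=1e-6):
    """Brute-force cross-covariance posterior via explicit inverse."""
    from scipy.spatial.distance import cdist

    y = np.asarray(y, float)

    def kern(a, b):
        d2 = cdist(a, b, "sqeuclidean")
        k = params.sigma_k2 * np.exp(-d2 / (2 * params.length_scale**2))
        k[d2 == 0.0] += jitter_frac * params.sigma_k2
        return k

    kn = kern(coords, coords) + params.sigma_n2 * np.eye(len(y))
    inv = np.linalg.inv(kn)
    kq = kern(query, coords)
    mean = params.mu_c + kq @ inv @ (y - params.mu_c)
    cov = kern(query, query) - kq @ inv @ kq.T
    return mean, cov
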