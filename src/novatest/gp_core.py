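"""Constant-mean RBF-kernel Gaussian-process regression for one gene.

Model: y = f(X) + eps, f ~ GP(mu_c, K), eps ~ N(0, sigma_n2 * I), with

    K(x, x') = sigma_k2 * exp(-||x - x'||^2 / (2 * l^2)).

Hyperparameters (mu_c, sigma_k2, l, sigma_n2) are fitted by minimizing the
negative log marginal likelihood with a quasi-Newton optimizer; the positive
parameters are optimized in log-space. Posterior prediction supports both the
training locations and held-out query locations via the standard
cross-covariance conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg
import scipy.optimize
from scipy.spatial.distance import cdist

__all__ = [
    "GPHyperParams",
    "GPPosterior",
    "ParameterError",
    "DegenerateInputError",
    "NumericalError",
    "GPFitError",
    "rbf_kernel",
    "negative_log_marginal_likelihood",
    "fit_homoscedastic_gp",
    "gp_posterior",
]

# Relative jitter added to the kernel diagonal before any factorization.
JITTER_FRAC = 1e-6

_LOG2PI = float(np.log(2.0 * np.pi))
_LOG_BOUND = 25.0  # bound on log-parameters during optimization


class ParameterError(ValueError):
    """Invalid (nonpositive) kernel parameter."""


class DegenerateInputError(ValueError):
    """Input data cannot support a fit (e.g. zero variance)."""


class NumericalError(RuntimeError):
    """Covariance factorization failed even after jitter."""


class GPFitError(RuntimeError):
    """Hyperparameter optimization failed on all restarts."""


@dataclass(frozen=True)
class GPHyperParams:
    """Fitted hyperparameters of a constant-mean RBF Gaussian process."""

    mu_c: float
    sigma_k2: float
    length_scale: float
    sigma_n2: float

    def __post_init__(self) -> None:
        if not (self.sigma_k2 > 0):
            raise ParameterError(f"sigma_k2 must be > 0, got {self.sigma_k2}")
        if not (self.length_scale > 0):
            raise ParameterError(f"length_scale must be > 0, got {self.length_scale}")
        if self.sigma_n2 < 0:
            raise ParameterError(f"sigma_n2 must be >= 0, got {self.sigma_n2}")


@dataclass
class GPPosterior:
    """Posterior mean and covariance of a GP evaluated at its training spots."""

    mean: np.ndarray
    cov: np.ndarray
    train_coords: np.ndarray
    params: GPHyperParams

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise NumericalError("posterior covariance is not symmetric")

    def variance(self) -> np.ndarray:
        """Posterior variance per spot (tiny negatives clipped to zero)."""
        return np.clip(np.diag(self.cov), 0.0, None)


def _sq_dists(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = a if b is None else np.asarray(b, dtype=float)
    return cdist(a, b, metric="sqeuclidean")


def rbf_kernel(
    a: np.ndarray, b: np.ndarray, sigma_k2: float, length_scale: float
) -> np.ndarray:
    """RBF (squared-exponential) kernel matrix between coordinate sets."""
    if not (sigma_k2 > 0):
        raise ParameterError(f"sigma_k2 must be > 0, got {sigma_k2}")
    if not (length_scale > 0):
        raise ParameterError(f"length_scale must be > 0, got {length_scale}")
    d2 = _sq_dists(a, b)
    return sigma_k2 * np.exp(-d2 / (2.0 * length_scale**2))


def _noisy_kernel(
    d2: np.ndarray, params: GPHyperParams, jitter_frac: float
) -> tuple[np.ndarray, np.ndarray]:
    """Return (K_jittered, K_noisy) where K_noisy = K + (sigma_n2) I."""
    k = params.sigma_k2 * np.exp(-d2 / (2.0 * params.length_scale**2))
    k[np.diag_indices_from(k)] += jitter_frac * params.sigma_k2
    kn = k.copy()
    kn[np.diag_indices_from(kn)] += params.sigma_n2
    return k, kn


def _chol(kn: np.ndarray) -> np.ndarray:
    try:
        return scipy.linalg.cholesky(kn, lower=True)
    except scipy.linalg.LinAlgError as exc:
        smallest = float(np.linalg.eigvalsh(kn)[0])
        raise NumericalError(
            f"covariance not positive definite after jitter "
            f"(smallest eigenvalue {smallest:.3e})"
        ) from exc


def negative_log_marginal_likelihood(
    y: np.ndarray,
    coords: np.ndarray,
    params: GPHyperParams,
    jitter_frac: float = JITTER_FRAC,
) -> float:
    """Negative log marginal likelihood of y under the homoscedastic GP.

    L1 = 1/2 (y-mu)^T (K + sigma_n2 I)^-1 (y-mu)
       + 1/2 log|K + sigma_n2 I| + N/2 log(2 pi)
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 1:
        raise DegenerateInputError("empty observation vector")
    d2 = _sq_dists(coords)
    _, kn = _noisy_kernel(d2, params, jitter_frac)
    low = _chol(kn)
    resid = y - params.mu_c
    alpha = scipy.linalg.cho_solve((low, True), resid)
    logdet = 2.0 * float(np.sum(np.log(np.diag(low))))
    return 0.5 * float(resid @ alpha) + 0.5 * logdet + 0.5 * n * _LOG2PI


def _nll_value_grad(
    theta: np.ndarray,
    y: np.ndarray,
    d2: np.ndarray,
    optimize_mean: bool,
    fixed_mean: float,
    jitter_frac: float,
) -> tuple[float, np.ndarray]:
    """Objective and gradient in (mu_c?, log sigma_k2, log l, log sigma_n2)."""
    n = y.shape[0]
    if optimize_mean:
        mu_c = theta[0]
        log_sk2, log_l, log_sn2 = theta[1:]
    else:
        mu_c = fixed_mean
        log_sk2, log_l, log_sn2 = theta
    sk2 = np.exp(log_sk2)
    lsq = np.exp(2.0 * log_l)
    sn2 = np.exp(log_sn2)

    k = sk2 * np.exp(-d2 / (2.0 * lsq))
    kj = jitter_frac * sk2
    kn = k.copy()
    kn[np.diag_indices_from(kn)] += kj + sn2
    try:
        low = scipy.linalg.cholesky(kn, lower=True)
    except scipy.linalg.LinAlgError:
        return np.inf, np.zeros_like(theta)
    resid = y - mu_c
    alpha = scipy.linalg.cho_solve((low, True), resid)
    logdet = 2.0 * float(np.sum(np.log(np.diag(low))))
    nll = 0.5 * float(resid @ alpha) + 0.5 * logdet + 0.5 * n * _LOG2PI

    kn_inv = scipy.linalg.cho_solve((low, True), np.eye(n))
    # dL/dtheta = 1/2 tr(W dK/dtheta), W = Kn^-1 - alpha alpha^T
    w = kn_inv - np.outer(alpha, alpha)
    dk_sk2 = k.copy()
    dk_sk2[np.diag_indices_from(dk_sk2)] += kj  # jitter scales with sigma_k2
    g_sk2 = 0.5 * float(np.sum(w * dk_sk2))
    g_l = 0.5 * float(np.sum(w * (k * d2 / lsq)))  # d/dlog l, since dlsq = 2 lsq dlog l
    g_sn2 = 0.5 * sn2 * float(np.trace(w))
    if optimize_mean:
        g_mu = -float(np.sum(alpha))
        return nll, np.array([g_mu, g_sk2, g_l, g_sn2])
    return nll, np.array([g_sk2, g_l, g_sn2])


def default_init(y: np.ndarray, coords: np.ndarray) -> GPHyperParams:
    """Scale-aware initial hyperparameters.

    mu_c = mean(y); sigma_k2 = sigma_n2 = var(y)/2;
    length_scale = median pairwise spot distance.
    """
    y = np.asarray(y, dtype=float)
    var = float(np.var(y))
    if var == 0.0:
        var = 1.0
    d = np.sqrt(_sq_dists(coords))
    med = float(np.median(d[np.triu_indices_from(d, k=1)]))
    if med <= 0:
        med = 1.0
    return GPHyperParams(
        mu_c=float(np.mean(y)),
        sigma_k2=var / 2.0,
        length_scale=med,
        sigma_n2=var / 2.0,
    )


def fit_homoscedastic_gp(
    y: np.ndarray,
    coords: np.ndarray,
    init: GPHyperParams | None = None,
    n_restarts: int = 2,
    seed: int = 0,
    optimize_mean: bool = True,
    fixed_mean: float = 0.0,
    jitter_frac: float = JITTER_FRAC,
    maxiter: int = 200,
) -> GPHyperParams:
    """Fit GP hyperparameters by minimizing the negative log likelihood.

    Runs ``n_restarts`` L-BFGS-B optimizations (first from ``init``, the rest
    from log-uniform perturbations of it, seeded) and returns the best
    parameter set; the result never has higher L1 than ``init``.

    Set ``optimize_mean=False`` to hold the prior mean fixed at
    ``fixed_mean`` (used for the zero-mean variance-residual GP).
    """
    y = np.asarray(y, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if y.shape[0] < 2:
        raise DegenerateInputError("need at least 2 observations")
    if optimize_mean and np.var(y) == 0.0:
        raise DegenerateInputError("y has zero variance")
    if init is None:
        init = default_init(y, coords)
        if not optimize_mean:
            init = replace(init, mu_c=fixed_mean)
    d2 = _sq_dists(coords)
    rng = np.random.default_rng(seed)

    def pack(p: GPHyperParams) -> np.ndarray:
        logs = [np.log(p.sigma_k2), np.log(p.length_scale), np.log(max(p.sigma_n2, 1e-10))]
        return np.array(([p.mu_c] if optimize_mean else []) + logs)

    def unpack(theta: np.ndarray) -> GPHyperParams:
        if optimize_mean:
            mu_c = float(theta[0])
            logs = theta[1:]
        else:
            mu_c = fixed_mean
            logs = theta
        return GPHyperParams(
            mu_c=mu_c,
            sigma_k2=float(np.exp(logs[0])),
            length_scale=float(np.exp(logs[1])),
            sigma_n2=float(np.exp(logs[2])),
        )

    theta0 = pack(init)
    nll0, _ = _nll_value_grad(theta0, y, d2, optimize_mean, fixed_mean, jitter_frac)
    bounds = ([(None, None)] if optimize_mean else []) + [(-_LOG_BOUND, _LOG_BOUND)] * 3

    starts = [theta0]
    for _ in range(max(0, n_restarts - 1)):
        pert = theta0.copy()
        off = 1 if optimize_mean else 0
        pert[off:] = pert[off:] + rng.uniform(-np.log(3.0), np.log(3.0), size=3)
        if optimize_mean:
            pert[0] += rng.normal(scale=0.1 * max(np.std(y), 1e-12))
        starts.append(pert)

    best_theta, best_val = theta0, nll0
    failures: list[str] = []
    any_success = False
    for start in starts:
        res = scipy.optimize.minimize(
            _nll_value_grad,
            np.clip(start, -_LOG_BOUND, _LOG_BOUND),
            args=(y, d2, optimize_mean, fixed_mean, jitter_frac),
            method="L-BFGS-B",
            jac=True,
            bounds=bounds,
            options={"maxiter": maxiter},
        )
        if np.isfinite(res.fun):
            any_success = True
            if res.fun < best_val:
                best_theta, best_val = res.x, float(res.fun)
        else:
            failures.append(str(res.message))
    if not any_success:
        raise GPFitError(
            f"all {len(starts)} optimizer restarts failed: {failures}"
        )
    return unpack(best_theta)


def gp_posterior(
    y: np.ndarray,
    coords: np.ndarray,
    params: GPHyperParams,
    query_coords: np.ndarray | None = None,
    jitter_frac: float = JITTER_FRAC,
):
    """GP posterior given training data.

    With ``query_coords=None`` the posterior over the training spots is
    returned as a :class:`GPPosterior`:

        mean = mu + K (K + sigma_n2 I)^-1 (y - mu)
        cov  = K - K (K + sigma_n2 I)^-1 K

    Otherwise the held-out predictive ``(mean, cov)`` tuple is returned using
    the cross-covariance form

        mean = mu + K(Q,X) (K + sigma_n2 I)^-1 (y - mu)
        cov  = K(Q,Q) - K(Q,X) (K + sigma_n2 I)^-1 K(X,Q).
    """
    y = np.asarray(y, dtype=float)
    coords = np.asarray(coords, dtype=float)
    d2 = _sq_dists(coords)
    k, kn = _noisy_kernel(d2, params, jitter_frac)
    low = _chol(kn)
    resid = y - params.mu_c
    alpha = scipy.linalg.cho_solve((low, True), resid)

    if query_coords is None:
        mean = params.mu_c + k @ alpha
        v = scipy.linalg.cho_solve((low, True), k)
        cov = k - k @ v
        cov = 0.5 * (cov + cov.T)
        np.fill_diagonal(cov, np.clip(np.diag(cov), 0.0, None))
        return GPPosterior(mean=mean, cov=cov, train_coords=coords, params=params)

    # The jittered kernel is treated as THE kernel everywhere, so predicting
    # at the training coordinates reproduces the training-posterior path.
    query = np.asarray(query_coords, dtype=float)
    kq = rbf_kernel(query, coords, params.sigma_k2, params.length_scale)
    kq[_sq_dists(query, coords) == 0.0] += jitter_frac * params.sigma_k2
    kqq = rbf_kernel(query, query, params.sigma_k2, params.length_scale)
    kqq[np.diag_indices_from(kqq)] += jitter_frac * params.sigma_k2
    mean = params.mu_c + kq @ alpha
    v = scipy.linalg.cho_solve((low, True), kq.T)
    cov = kqq - kq @ v
    cov = 0.5 * (cov + cov.T)
    np.fill_diagonal(cov, np.clip(np.diag(cov), 0.0, None))
    return mean, cov
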