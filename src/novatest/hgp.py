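"""Approximate heteroscedastic GP built from two homoscedastic GPs.

Stage 1 fits a regular homoscedastic GP to the expression values and computes
its posterior at the training spots. Stage 2 forms the variance-residual
dataset

    z_i = (y_i - mu_GP,i)^2 - Sigma_GP(i, i)

and fits a second, zero-mean homoscedastic GP to z. The heteroscedastic fit
keeps the stage-1 mean and refines only the variance:

    mu_HGP = mu_GP,   sigma_HGP^2 = max(0, diag(Sigma_GP) + mu_GPv)

where mu_GPv is the stage-2 posterior mean. Held-out prediction applies the
same combination at the query locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gp_core import (
    GPFitError,
    GPHyperParams,
    GPPosterior,
    DegenerateInputError,
    fit_homoscedastic_gp,
    gp_posterior,
)

__all__ = [
    "VarianceResidualDataset",
    "HGPFit",
    "StructuralError",
    "variance_residuals",
    "fit_hgp",
    "hgp_predict",
]

MIN_SPOTS = 20


class StructuralError(ValueError):
    """Shape mismatch between inputs."""


@dataclass
class VarianceResidualDataset:
    """Per-spot difference between empirical and posterior variance."""

    z: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(self.z)):
            raise StructuralError("non-finite variance residuals")


@dataclass
class HGPFit:
    """Heteroscedastic fit: stage-1 mean plus clipped per-spot variance."""

    mean: np.ndarray
    noise_variance: np.ndarray
    first_gp: GPPosterior
    variance_gp_params: GPHyperParams
    y: np.ndarray
    z: np.ndarray
    coords: np.ndarray
    params: GPHyperParams


def variance_residuals(y: np.ndarray, posterior: GPPosterior) -> VarianceResidualDataset:
    """z_i = (y_i - mu_GP,i)^2 - Sigma_GP(i,i)."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] != posterior.mean.shape[0]:
        raise StructuralError(
            f"y has {y.shape[0]} spots but posterior has {posterior.mean.shape[0]}"
        )
    z = (y - posterior.mean) ** 2 - np.diag(posterior.cov)
    return VarianceResidualDataset(z=z, coords=posterior.train_coords)


def fit_hgp(
    y: np.ndarray,
    coords: np.ndarray,
    seed: int = 0,
    n_restarts: int = 2,
    stage1_params: GPHyperParams | None = None,
    min_spots: int = MIN_SPOTS,
) -> HGPFit:
    """Two-stage approximate heteroscedastic GP fit.

    ``stage1_params`` lets callers reuse an already-fitted homoscedastic GP
    (the stage-1 model is identical to it); otherwise stage 1 is fitted here.
    """
    y = np.asarray(y, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if y.shape[0] < min_spots:
        raise DegenerateInputError(
            f"need at least {min_spots} spots for two-stage fitting, got {y.shape[0]}"
        )
    try:
        if stage1_params is None:
            stage1_params = fit_homoscedastic_gp(y, coords, seed=seed, n_restarts=n_restarts)
        post = gp_posterior(y, coords, stage1_params)
    except (GPFitError, DegenerateInputError) as exc:
        raise type(exc)(f"stage 1 (mean GP): {exc}") from exc

    dv = variance_residuals(y, post)
    try:
        var_params = fit_homoscedastic_gp(
            dv.z,
            coords,
            seed=seed + 1,
            n_restarts=n_restarts,
            optimize_mean=False,
            fixed_mean=0.0,
        )
        mu_gpv = gp_posterior(dv.z, coords, var_params).mean
    except (GPFitError, DegenerateInputError) as exc:
        raise type(exc)(f"stage 2 (variance GP): {exc}") from exc

    sigma_hgp2 = np.clip(post.variance() + mu_gpv, 0.0, None)
    return HGPFit(
        mean=post.mean,
        noise_variance=sigma_hgp2,
        first_gp=post,
        variance_gp_params=var_params,
        y=y,
        z=dv.z,
        coords=coords,
        params=stage1_params,
    )


def hgp_predict(fit: HGPFit, query_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and heteroscedastic variance at query locations.

    mean comes from the stage-1 GP posterior; variance is
    max(0, stage-1 posterior variance + stage-2 posterior mean of z).
    """
    query = np.asarray(query_coords, dtype=float)
    mean, cov = gp_posterior(fit.y, fit.coords, fit.params, query)
    mu_gpv, _ = gp_posterior(fit.z, fit.coords, fit.variance_gp_params, query)
    variance = np.clip(np.clip(np.diag(cov), 0.0, None) + mu_gpv, 0.0, None)
    return mean, variance
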