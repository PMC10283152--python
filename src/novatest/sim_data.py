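"""Synthetic spatial expression with controlled mean and noise-variance fields.

Generates spot grids, GP-smooth (or simpler) spatial mean fields, and
Gaussian noise whose variance is either constant or varies with location
(linear ramp, half-plane step, or a log-GP field). Ground-truth mean and
variance maps are returned alongside the data so recovery can be scored.
Count-valued matrices for the I/O path are produced by inverting the
Anscombe transform and Poisson sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .gp_core import rbf_kernel
from .st_io import ANSCOMBE_OFFSET, SpatialCountMatrix, coordinate_spot_ids

__all__ = [
    "SimSpec",
    "make_coords",
    "simulate_gene",
    "simulate_cohort",
    "counts_from_expression",
]

MIN_SPOTS = 20


@dataclass
class SimSpec:
    """Specification of one simulated gene's spatial field.

    mean_fn kinds: ``{"kind": "gp", "sigma_k2": v, "length_scale": l}``,
    ``{"kind": "constant", "value": c}``,
    ``{"kind": "ramp", "axis": 0|1, "low": a, "high": b}``.

    noise_fn kinds: ``{"kind": "constant", "variance": v}``,
    ``{"kind": "ramp", "axis": 0|1, "v_low": a, "v_high": b}`` (optionally
    ``"reverse": True`` so variance decreases along the axis),
    ``{"kind": "step", "axis": 0|1, "v_low": a, "v_high": b, "boundary": q}``
    with the boundary a quantile in (0, 1) of the axis coordinate, and
    ``{"kind": "gp-log-variance", "sigma_k2": v, "length_scale": l,
    "base_variance": b}``.
    """

    n_spots: int = 200
    grid: str = "square"
    mean_fn: dict[str, Any] = field(
        default_factory=lambda: {"kind": "gp", "sigma_k2": 1.0, "length_scale": 0.3}
    )
    noise_fn: dict[str, Any] = field(
        default_factory=lambda: {"kind": "constant", "variance": 0.25}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spots < MIN_SPOTS:
            raise ValueError(f"n_spots must be >= {MIN_SPOTS}")
        if self.grid not in ("square", "hexagonal", "random-uniform"):
            raise ValueError(f"unknown grid {self.grid!r}")


def make_coords(spec: SimSpec) -> np.ndarray:
    """Deterministic spot coordinates in (approximately) the unit square."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_spots
    if spec.grid == "random-uniform":
        coords = rng.uniform(0.0, 1.0, size=(n, 2))
        while len(np.unique(coords, axis=0)) < n:  # pragma: no cover
            coords = rng.uniform(0.0, 1.0, size=(n, 2))
        return coords
    side = int(np.ceil(np.sqrt(n)))
    xs = np.linspace(0.0, 1.0, side)
    ys = np.linspace(0.0, 1.0, side)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    if spec.grid == "hexagonal":
        dx = (xs[1] - xs[0]) / 2.0 if side > 1 else 0.0
        gx = gx + dx * (np.arange(side)[:, None] % 2)
    coords = np.column_stack([gx.ravel(), gy.ravel()])[:n]
    return coords


def _axis_unit(coords: np.ndarray, axis: int) -> np.ndarray:
    """Coordinate along ``axis`` rescaled to [0, 1]."""
    c = coords[:, axis]
    span = np.ptp(c)
    return (c - c.min()) / span if span > 0 else np.zeros_like(c)


def _mean_field(spec: SimSpec, coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    fn = spec.mean_fn
    kind = fn["kind"]
    n = coords.shape[0]
    if kind == "constant":
        return np.full(n, float(fn.get("value", 0.0)))
    if kind == "ramp":
        u = _axis_unit(coords, int(fn.get("axis", 0)))
        return float(fn.get("low", 0.0)) + (float(fn.get("high", 1.0)) - float(fn.get("low", 0.0))) * u
    if kind == "gp":
        k = rbf_kernel(coords, coords, float(fn["sigma_k2"]), float(fn["length_scale"]))
        k[np.diag_indices_from(k)] += 1e-8 * float(fn["sigma_k2"])
        low = np.linalg.cholesky(k)
        return float(fn.get("offset", 0.0)) + low @ rng.standard_normal(n)
    raise ValueError(f"unknown mean_fn kind {kind!r}")


def _variance_field(spec: SimSpec, coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    fn = spec.noise_fn
    kind = fn["kind"]
    n = coords.shape[0]
    if kind == "constant":
        v = float(fn["variance"])
        if v <= 0:
            raise ValueError("noise variance must be positive")
        return np.full(n, v)
    if kind == "ramp":
        u = _axis_unit(coords, int(fn.get("axis", 0)))
        if fn.get("reverse", False):
            u = 1.0 - u
        v_low, v_high = float(fn["v_low"]), float(fn["v_high"])
        if v_low <= 0 or v_high <= 0:
            raise ValueError("noise variances must be positive")
        return v_low + (v_high - v_low) * u
    if kind == "step":
        u = _axis_unit(coords, int(fn.get("axis", 0)))
        boundary = float(fn.get("boundary", 0.5))
        cut = np.quantile(u, boundary)
        v_low, v_high = float(fn["v_low"]), float(fn["v_high"])
        if v_low <= 0 or v_high <= 0:
            raise ValueError("noise variances must be positive")
        return np.where(u <= cut, v_low, v_high)
    if kind == "gp-log-variance":
        k = rbf_kernel(coords, coords, float(fn["sigma_k2"]), float(fn["length_scale"]))
        k[np.diag_indices_from(k)] += 1e-8 * float(fn["sigma_k2"])
        low = np.linalg.cholesky(k)
        return float(fn.get("base_variance", 1.0)) * np.exp(low @ rng.standard_normal(n))
    raise ValueError(f"unknown noise_fn kind {kind!r}")


def simulate_gene(
    spec: SimSpec, coords: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one gene: y_i = f(x_i) + N(0, g(x_i)).

    Returns ``(y, true_mean, true_var)``; all deterministic given the spec's
    seed (and the supplied coordinates, if any).
    """
    if coords is None:
        coords = make_coords(spec)
    coords = np.asarray(coords, dtype=float)
    rng = np.random.default_rng(spec.seed)
    true_mean = _mean_field(spec, coords, rng)
    true_var = _variance_field(spec, coords, rng)
    y = true_mean + rng.standard_normal(coords.shape[0]) * np.sqrt(true_var)
    return y, true_mean, true_var


def simulate_cohort(
    n_null: int,
    n_noisy: int,
    spec_null: SimSpec,
    spec_noisy: SimSpec,
    coords: np.ndarray | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """Independent null + noisy genes on shared coordinates.

    Per-gene seeds are derived from the cohort seed (``spec_null.seed`` unless
    ``seed`` is given) so the cohort is reproducible and order-independent.
    Returns a dict with keys ``values`` (N x G), ``coords``, ``gene_names``,
    ``labels`` (bool array, True = noisy), ``true_means``, ``true_vars``.
    """
    from dataclasses import replace

    cohort_seed = spec_null.seed if seed is None else seed
    if coords is None:
        coords = make_coords(replace(spec_null, seed=cohort_seed))
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    g = n_null + n_noisy
    values = np.empty((n, g))
    true_means = np.empty((n, g))
    true_vars = np.empty((n, g))
    labels = np.zeros(g, dtype=bool)
    gene_names = []
    for j in range(g):
        noisy = j >= n_null
        base = spec_noisy if noisy else spec_null
        gene_seed = int(np.random.SeedSequence((cohort_seed, j)).generate_state(1)[0])
        y, mu, var = simulate_gene(replace(base, seed=gene_seed), coords)
        values[:, j] = y
        true_means[:, j] = mu
        true_vars[:, j] = var
        labels[j] = noisy
        gene_names.append(f"{'noisy' if noisy else 'null'}_gene_{j:04d}")
    return {
        "values": values,
        "coords": coords,
        "gene_names": gene_names,
        "labels": labels,
        "true_means": true_means,
        "true_vars": true_vars,
    }


def counts_from_expression(
    values: np.ndarray,
    coords: np.ndarray,
    gene_names: list[str],
    seed: int = 0,
    library_factor_sd: float = 0.3,
) -> SpatialCountMatrix:
    """Count matrix for the I/O path: inverse-Anscombe then Poisson sampling.

    Per-spot library-size variation is introduced via lognormal scaling
    factors, emulating UMI depth differences between spots.
    """
    rng = np.random.default_rng(seed)
    lam = np.clip((np.asarray(values, dtype=float) / 2.0) ** 2 - ANSCOMBE_OFFSET, 0.0, None)
    factors = rng.lognormal(mean=0.0, sigma=library_factor_sd, size=lam.shape[0])
    counts = rng.poisson(lam * factors[:, None])
    return SpatialCountMatrix(
        counts=counts.astype(np.int64),
        coords=np.asarray(coords, dtype=float),
        gene_names=list(gene_names),
        spot_ids=coordinate_spot_ids(coords),
    )
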