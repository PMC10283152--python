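"""Repeated-split NLPD comparison of the two GP models and noisy-gene calling.

For each gene, the homoscedastic GP and the approximate heteroscedastic GP
are fitted on R random 90/10 train/validation splits (both models always see
identical splits) and scored by the negative log predictive density (NLPD)
of the held-out spots. A one-sided Wilcoxon signed-rank test on the R paired
NLPD values, followed by Benjamini-Hochberg FDR correction across genes,
flags genes whose heteroscedastic NLPD is significantly lower ("noisy"
genes).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from . import hgp as hgp_mod
from .gp_core import DegenerateInputError, GPFitError, fit_homoscedastic_gp, gp_posterior

__all__ = [
    "SplitPlan",
    "NoiseTestResult",
    "GeneFailure",
    "nlpd",
    "evaluate_gene",
    "wilcoxon_signed_rank",
    "bh_fdr",
    "call_noisy_genes",
    "run_noise_test",
    "gene_seed",
]

VAR_FLOOR = 1e-8
# The clipped heteroscedastic variance max(0, .) can reach (numerically) zero
# at validation spots, which makes NLPD arbitrarily large for any nonzero
# residual and would bias the test against the heteroscedastic model. Its
# predictive variance is therefore floored at this fraction of the fitted
# homoscedastic noise level.
HET_VAR_FLOOR_FRAC = 0.15
EXACT_WILCOXON_MAX_R = 25


@dataclass
class SplitPlan:
    """Shared train/validation split indices used for every gene."""

    n_repeats: int
    train_fraction: float
    seed: int
    splits: list[tuple[np.ndarray, np.ndarray]]

    @classmethod
    def make(
        cls,
        n_spots: int,
        n_repeats: int = 10,
        train_fraction: float = 0.9,
        seed: int = 0,
    ) -> "SplitPlan":
        if not (0.0 < train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        n_val = int(round((1.0 - train_fraction) * n_spots))
        if n_val < 2:
            raise ValueError(
                f"validation set would have {n_val} spots (< 2); "
                f"increase n_spots or decrease train_fraction"
            )
        rng = np.random.default_rng(seed)
        splits = []
        for _ in range(n_repeats):
            perm = rng.permutation(n_spots)
            splits.append((np.sort(perm[n_val:]), np.sort(perm[:n_val])))
        return cls(n_repeats=n_repeats, train_fraction=train_fraction, seed=seed, splits=splits)


@dataclass
class NoiseTestResult:
    """Per-gene outcome of the noise-variance test."""

    gene: str
    nlpd_homo: np.ndarray
    nlpd_hetero: np.ndarray
    p_value: float
    q_value: float
    is_noisy: bool


@dataclass
class GeneFailure:
    gene: str
    split_index: int
    reason: str


def gene_seed(base_seed: int, gene: str) -> int:
    """Deterministic, order-independent per-gene seed."""
    digest = hashlib.sha256(f"{base_seed}:{gene}".encode()).digest()
    return int.from_bytes(digest[:8], "little")


def nlpd(
    y_val: np.ndarray,
    pred_mean: np.ndarray,
    pred_var: np.ndarray,
    var_floor: float = VAR_FLOOR,
) -> float:
    """Average negative log predictive density of held-out observations.

    (1/N') * sum_i 1/2 [ log(2 pi var_i) + (y_i - mean_i)^2 / var_i ]
    """
    y_val = np.asarray(y_val, dtype=float)
    pred_mean = np.asarray(pred_mean, dtype=float)
    pred_var = np.maximum(np.asarray(pred_var, dtype=float), var_floor)
    if np.any(pred_var <= 0):
        raise FloatingPointError("nonpositive predictive variance after flooring")
    resid2 = (y_val - pred_mean) ** 2
    return float(np.mean(0.5 * (np.log(2.0 * np.pi * pred_var) + resid2 / pred_var)))


def evaluate_gene(
    y: np.ndarray,
    coords: np.ndarray,
    plan: SplitPlan,
    seed: int = 0,
    n_restarts: int = 2,
    het_var_floor_frac: float = HET_VAR_FLOOR_FRAC,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired validation NLPD vectors (homoscedastic, heteroscedastic).

    Per split: fit the homoscedastic GP on the training spots and score the
    validation spots with predictive variance = posterior variance + sigma_n2;
    fit the heteroscedastic model on the same training spots (reusing the
    homoscedastic fit as its stage 1) and score with its per-spot variance
    floored at ``het_var_floor_frac * sigma_n2``.

    Raises
    ------
    GPFitError / DegenerateInputError
        Tagged with the failing split index; the caller is expected to log
        and exclude the gene.
    """
    y = np.asarray(y, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if np.var(y) == 0.0:
        raise DegenerateInputError("gene has zero variance across spots")
    nlpd_homo = np.empty(plan.n_repeats)
    nlpd_het = np.empty(plan.n_repeats)
    for r, (tr, va) in enumerate(plan.splits):
        try:
            params = fit_homoscedastic_gp(
                y[tr], coords[tr], seed=seed + 1000003 * r, n_restarts=n_restarts
            )
            mean_h, cov_h = gp_posterior(y[tr], coords[tr], params, coords[va])
            var_h = np.clip(np.diag(cov_h), 0.0, None) + params.sigma_n2
            nlpd_homo[r] = nlpd(y[va], mean_h, var_h)

            fit = hgp_mod.fit_hgp(
                y[tr],
                coords[tr],
                seed=seed + 1000003 * r,
                n_restarts=n_restarts,
                stage1_params=params,
            )
            mean_g, var_g = hgp_mod.hgp_predict(fit, coords[va])
            var_g = np.maximum(var_g, het_var_floor_frac * params.sigma_n2)
            nlpd_het[r] = nlpd(y[va], mean_g, var_g)
        except (GPFitError, DegenerateInputError) as exc:
            raise type(exc)(f"split {r}: {exc}") from exc
    return nlpd_homo, nlpd_het


def wilcoxon_signed_rank(
    a: np.ndarray, b: np.ndarray, alternative: str = "less"
) -> float:
    """Wilcoxon signed-rank p-value for paired samples a vs b.

    ``alternative="less"`` tests whether a is stochastically smaller than b.
    Zero differences are discarded before ranking; if every difference is
    zero the p-value is 1. The exact null distribution is used for
    R <= 25 (no normal approximation).
    """
    if alternative not in ("less", "two-sided"):
        raise ValueError(f"unsupported alternative {alternative!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.shape[0] < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    method = "exact" if d.size <= EXACT_WILCOXON_MAX_R else "approx"
    res = scipy.stats.wilcoxon(
        d, zero_method="wilcox", alternative=alternative, method=method
    )
    return float(res.pvalue)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_noisy_genes(
    results: dict[str, tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
) -> list[NoiseTestResult]:
    """Wilcoxon per gene (alternative "less"), BH across genes, flag q < alpha."""
    if not results:
        raise ValueError("no genes with valid NLPD vectors")
    genes = list(results.keys())
    # results map gene -> (nlpd_homo, nlpd_hetero); test hetero < homo
    p = np.array(
        [wilcoxon_signed_rank(results[g][1], results[g][0], "less") for g in genes]
    )
    q = bh_fdr(p)
    out = []
    for i, g in enumerate(genes):
        homo, het = results[g]
        out.append(
            NoiseTestResult(
                gene=g,
                nlpd_homo=np.asarray(homo, dtype=float),
                nlpd_hetero=np.asarray(het, dtype=float),
                p_value=float(p[i]),
                q_value=float(q[i]),
                is_noisy=bool(q[i] < alpha),
            )
        )
    return out


def run_noise_test(
    values: np.ndarray,
    coords: np.ndarray,
    gene_names: list[str],
    plan: SplitPlan,
    alpha: float = 0.05,
    base_seed: int = 0,
    n_restarts: int = 2,
) -> tuple[list[NoiseTestResult], list[GeneFailure]]:
    """Evaluate every gene column of ``values`` and call noisy genes.

    Genes whose fit fails on any split are excluded with a logged reason.
    """
    values = np.asarray(values, dtype=float)
    nlpds: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    failures: list[GeneFailure] = []
    for j, gene in enumerate(gene_names):
        try:
            nlpds[gene] = evaluate_gene(
                values[:, j],
                coords,
                plan,
                seed=gene_seed(base_seed, gene),
                n_restarts=n_restarts,
            )
        except (GPFitError, DegenerateInputError) as exc:
            failures.append(GeneFailure(gene=gene, split_index=-1, reason=str(exc)))
    if not nlpds:
        return [], failures
    return call_noisy_genes(nlpds, alpha=alpha), failures
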