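"""Explanatory variables for noise-variance patterns and their association.

Provides the cell-abundance proxy (total transcript count per spot), a
marker-set enrichment score against expression-binned control gene sets
(yielding a per-spot cell-type-heterogeneity count), Spearman association of
noise-variance maps with an explanatory variable, and a local mean-variance
correlation diagnostic over each spot's nearest neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial import cKDTree

from .noise_test import bh_fdr
from .st_io import NormalizedExpression, SpatialCountMatrix

__all__ = [
    "MarkerSets",
    "EnrichmentResult",
    "ExplanatoryAssociation",
    "read_marker_sets",
    "cell_abundance",
    "enrichment_pvalues",
    "bivariate_association",
    "local_mean_variance_correlation",
]

DEFAULT_RHO_THRESHOLD = 0.35
ENRICHMENT_ALPHA = 0.05


@dataclass
class MarkerSets:
    """Marker gene lists per cell type (e.g. top 20 per type)."""

    sets: dict[str, list[str]]

    def restrict_to(self, genes: list[str]) -> tuple["MarkerSets", dict[str, list[str]]]:
        """Drop markers absent from ``genes``; returns (restricted, dropped)."""
        present = set(genes)
        kept: dict[str, list[str]] = {}
        dropped: dict[str, list[str]] = {}
        for ct, markers in self.sets.items():
            kept[ct] = [m for m in markers if m in present]
            missing = [m for m in markers if m not in present]
            if missing:
                dropped[ct] = missing
        return MarkerSets(kept), dropped


@dataclass
class EnrichmentResult:
    """Per-spot enrichment p-values per cell type and the heterogeneity count."""

    p_values: pd.DataFrame  # spots x cell types, values in [0, 1]
    enriched: pd.DataFrame  # boolean, p < 0.05
    cell_type_count: np.ndarray  # per-spot number of enriched cell types


@dataclass
class ExplanatoryAssociation:
    """Per-gene Spearman association with one explanatory variable."""

    table: pd.DataFrame  # index gene, columns rho, p, q, flagged
    rho_threshold: float


def read_marker_sets(path: str | Path) -> MarkerSets:
    """Read a two-column TSV (cell_type, gene) into marker sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (cell_type, gene)")
    ct_col, gene_col = df.columns[:2]
    sets: dict[str, list[str]] = {}
    for ct, sub in df.groupby(ct_col, sort=False):
        sets[str(ct)] = [str(g) for g in sub[gene_col]]
    return MarkerSets(sets)


def cell_abundance(data: SpatialCountMatrix) -> np.ndarray:
    """Total transcript count per spot: a proxy for cell abundance."""
    return data.counts.sum(axis=1)


def enrichment_pvalues(
    expr: NormalizedExpression,
    markers: MarkerSets,
    n_controls: int = 1000,
    n_bins: int = 50,
    seed: int = 0,
) -> EnrichmentResult:
    """Marker-set enrichment per spot against expression-binned controls.

    The program score of a cell type at a spot is the mean expression of its
    marker set. Each of ``n_controls`` control sets replaces every marker
    with a random gene drawn (with replacement) from the same
    aggregate-expression bin; the p-value is the fraction of control scores
    strictly greater than the program score. A spot is enriched for a cell
    type if p < 0.05, and ``cell_type_count`` counts enriched types per spot.
    """
    rng = np.random.default_rng(seed)
    gene_index = {g: j for j, g in enumerate(expr.gene_names)}
    markers, dropped = markers.restrict_to(expr.gene_names)
    for ct, miss in dropped.items():
        if not markers.sets.get(ct):
            raise ValueError(f"marker set {ct!r} has no genes in the expression matrix")

    # Equal-frequency bins of aggregate (summed) expression across spots.
    aggregate = expr.values.sum(axis=0)
    n_bins_eff = min(n_bins, len(np.unique(aggregate)))
    bin_ids = pd.qcut(aggregate, q=n_bins_eff, labels=False, duplicates="drop")
    bin_members: dict[int, np.ndarray] = {
        b: np.flatnonzero(bin_ids == b) for b in np.unique(bin_ids)
    }

    n_spots = expr.n_spots
    cell_types = list(markers.sets.keys())
    pmat = np.ones((n_spots, len(cell_types)))
    for t, ct in enumerate(cell_types):
        idx = np.array([gene_index[m] for m in markers.sets[ct]])
        program = expr.values[:, idx].mean(axis=1)
        marker_bins = bin_ids[idx]
        # controls[c, m] = index of the gene standing in for marker m in control set c
        controls = np.empty((n_controls, idx.size), dtype=int)
        for m, b in enumerate(marker_bins):
            controls[:, m] = rng.choice(bin_members[b], size=n_controls, replace=True)
        exceed = np.zeros(n_spots, dtype=int)
        for c in range(n_controls):
            control_score = expr.values[:, controls[c]].mean(axis=1)
            exceed += control_score > program
        pmat[:, t] = exceed / n_controls

    p_df = pd.DataFrame(pmat, index=expr.spot_ids, columns=cell_types)
    enriched = p_df < ENRICHMENT_ALPHA
    return EnrichmentResult(
        p_values=p_df,
        enriched=enriched,
        cell_type_count=enriched.to_numpy().sum(axis=1),
    )


def bivariate_association(
    variance_maps: dict[str, np.ndarray],
    explanatory: np.ndarray,
    rho_threshold: float = DEFAULT_RHO_THRESHOLD,
) -> ExplanatoryAssociation:
    """Spearman correlation of each gene's noise-variance map with a covariate.

    Genes are flagged when |rho| exceeds ``rho_threshold`` and the BH-adjusted
    p-value is below 0.05.
    """
    explanatory = np.asarray(explanatory, dtype=float)
    if np.all(explanatory == explanatory[0]):
        raise ValueError("explanatory variable is constant; association undefined")
    genes = list(variance_maps.keys())
    rho = np.empty(len(genes))
    p = np.empty(len(genes))
    for i, g in enumerate(genes):
        vmap = np.asarray(variance_maps[g], dtype=float)
        if vmap.shape != explanatory.shape:
            raise ValueError(f"gene {g!r}: map not aligned with explanatory variable")
        res = scipy.stats.spearmanr(vmap, explanatory)
        rho[i] = res.statistic
        p[i] = res.pvalue
    rho = np.nan_to_num(rho, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    q = bh_fdr(p)
    flagged = (np.abs(rho) > rho_threshold) & (q < 0.05)
    table = pd.DataFrame(
        {"rho": rho, "p": p, "q": q, "flagged": flagged}, index=pd.Index(genes, name="gene")
    )
    return ExplanatoryAssociation(table=table, rho_threshold=rho_threshold)


def local_mean_variance_correlation(
    mean_map: np.ndarray,
    var_map: np.ndarray,
    coords: np.ndarray,
    n_neighbors: int = 12,
) -> np.ndarray:
    """Per-spot Spearman correlation of mean vs variance over nearby spots.

    For each spot, the correlation is computed over its ``n_neighbors``
    Euclidean nearest spots (the focal spot itself is excluded).
    """
    mean_map = np.asarray(mean_map, dtype=float)
    var_map = np.asarray(var_map, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n <= n_neighbors:
        raise ValueError(f"need more than {n_neighbors} spots, got {n}")
    tree = cKDTree(coords)
    _, nbr = tree.query(coords, k=n_neighbors + 1)
    out = np.empty(n)
    for i in range(n):
        idx = [j for j in nbr[i] if j != i][:n_neighbors]
        res = scipy.stats.spearmanr(mean_map[idx], var_map[idx])
        out[i] = res.statistic
    return out
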