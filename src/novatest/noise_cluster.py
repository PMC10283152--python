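"""Cluster noisy genes by the spatial pattern of their fitted noise variance.

Each gene's per-spot noise-variance map is binarized at an Otsu threshold,
pairwise Jaccard distances between the binary masks are computed, and
agglomerative hierarchical clustering on that distance matrix is cut at k
clusters. Cluster representatives are the per-cluster means of the raw
(un-binarized) variance maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy
from scipy.spatial.distance import squareform
from skimage.filters import threshold_otsu
from sklearn.metrics import silhouette_score

__all__ = [
    "BinarizedVarianceMap",
    "NoiseClustering",
    "DegenerateInputError",
    "otsu_threshold",
    "binarize_variance_map",
    "jaccard_distance",
    "cluster_noisy_genes",
    "silhouette_scan",
]

OTSU_NBINS = 256


class DegenerateInputError(ValueError):
    """Constant input cannot be thresholded."""


@dataclass
class BinarizedVarianceMap:
    gene: str
    mask: np.ndarray
    threshold: float


@dataclass
class NoiseClustering:
    """k-cluster partition of noisy genes with per-cluster mean variance maps."""

    labels: dict[str, int]
    k: int
    representatives: np.ndarray  # (k, N), row c-1 is the mean map of cluster c
    distance_matrix: np.ndarray  # (n_genes, n_genes) Jaccard distances
    genes: list[str]
    masks: dict[str, np.ndarray]
    degenerate_genes: list[str]


def otsu_threshold(values: np.ndarray, nbins: int = OTSU_NBINS) -> float:
    """Threshold maximizing between-class variance over an nbins histogram."""
    values = np.asarray(values, dtype=float)
    if values.size == 0 or np.ptp(values) == 0:
        raise DegenerateInputError("cannot threshold a constant vector")
    return float(threshold_otsu(values, nbins=nbins))


def binarize_variance_map(gene: str, values: np.ndarray) -> BinarizedVarianceMap:
    t = otsu_threshold(values)
    return BinarizedVarianceMap(gene=gene, mask=np.asarray(values) > t, threshold=t)


def jaccard_distance(a: np.ndarray, b: np.ndarray) -> float:
    """JD = 1 - |a AND b| / |a OR b|.

    Two all-false masks return 0 by convention (an all-false mask against a
    nonempty one returns 1).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must have equal length")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return 1.0 - np.count_nonzero(a & b) / union


def cluster_noisy_genes(
    variance_maps: dict[str, np.ndarray],
    k: int,
    linkage: str = "average",
) -> NoiseClustering:
    """Otsu-binarize, build the Jaccard-distance matrix, and cut at k clusters.

    Genes with constant variance maps cannot be binarized and are excluded
    (recorded in ``degenerate_genes``).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if linkage not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    masks: dict[str, np.ndarray] = {}
    degenerate: list[str] = []
    for gene, vmap in variance_maps.items():
        try:
            masks[gene] = binarize_variance_map(gene, vmap).mask
        except DegenerateInputError:
            degenerate.append(gene)
    genes = list(masks.keys())
    if len(genes) < k:
        raise ValueError(f"only {len(genes)} usable genes for k={k} clusters")

    n = len(genes)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = jaccard_distance(masks[genes[i]], masks[genes[j]])

    if n == k:
        label_arr = np.arange(1, n + 1)
    else:
        z = scipy.cluster.hierarchy.linkage(squareform(dist, checks=False), method=linkage)
        label_arr = scipy.cluster.hierarchy.fcluster(z, t=k, criterion="maxclust")
    labels = {g: int(c) for g, c in zip(genes, label_arr)}

    n_spots = len(next(iter(variance_maps.values())))
    reps = np.zeros((k, n_spots))
    for c in range(1, k + 1):
        members = [g for g in genes if labels[g] == c]
        reps[c - 1] = np.mean([variance_maps[g] for g in members], axis=0)
    return NoiseClustering(
        labels=labels,
        k=k,
        representatives=reps,
        distance_matrix=dist,
        genes=genes,
        masks=masks,
        degenerate_genes=degenerate,
    )


def silhouette_scan(
    variance_maps: dict[str, np.ndarray],
    k_range: range = range(2, 9),
    linkage: str = "average",
) -> dict[int, float]:
    """Mean silhouette width over the Jaccard distance matrix for each k."""
    scores: dict[int, float] = {}
    for k in k_range:
        try:
            clustering = cluster_noisy_genes(variance_maps, k=k, linkage=linkage)
        except ValueError:
            continue
        labels = np.array([clustering.labels[g] for g in clustering.genes])
        if len(set(labels)) < 2:
            continue
        scores[k] = float(
            silhouette_score(clustering.distance_matrix, labels, metric="precomputed")
        )
    return scores
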