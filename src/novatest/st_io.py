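"""Spatial count-matrix I/O, QC filtering, and variance-stabilizing normalization.

Supported on-disk formats:

* dense TSV: rows are spots, columns are genes, first column holds the spot
  identifier. Spot identifiers of the form ``"<x1>x<x2>"`` (e.g. ``"12x34"``)
  encode the spot coordinates directly; otherwise a separate coordinate table
  (``spot_id``, ``x1``, ``x2``) must be supplied.
* MatrixMarket triplet: a ``.mtx`` file (spots x genes) plus sidecar files
  listing gene names and spot identifiers (one per line) and a coordinate TSV.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "SpatialCountMatrix",
    "NormalizedExpression",
    "StIOError",
    "ParseError",
    "FormatError",
    "StructuralError",
    "DegenerateOutputError",
    "read_counts",
    "write_counts",
    "qc_filter",
    "normalize_and_stabilize",
    "write_normalized",
    "write_qc_report",
]

ANSCOMBE_OFFSET = 3.0 / 8.0
DEFAULT_DROP_PREFIXES = ("ERCC", "MT-")


class StIOError(ValueError):
    """Base class for spatial I/O errors."""


class ParseError(StIOError):
    """A spot identifier could not be parsed into coordinates."""


class FormatError(StIOError):
    """File content violates the expected format (e.g. non-integer counts)."""


class StructuralError(StIOError):
    """Dimension mismatch or otherwise malformed file structure."""


class DegenerateOutputError(StIOError):
    """An operation would produce an empty/degenerate result."""


@dataclass
class SpatialCountMatrix:
    """Raw UMI counts (N spots x G genes) with per-spot 2-D coordinates."""

    counts: np.ndarray
    coords: np.ndarray
    gene_names: list[str]
    spot_ids: list[str]
    qc_log: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        self.gene_names = list(self.gene_names)
        self.spot_ids = list(self.spot_ids)
        n, g = self.counts.shape
        if self.coords.shape != (n, 2):
            raise StructuralError(
                f"coords shape {self.coords.shape} does not match {n} spots"
            )
        if len(self.gene_names) != g:
            raise StructuralError(
                f"{len(self.gene_names)} gene names for {g} matrix columns"
            )
        if len(self.spot_ids) != n:
            raise StructuralError(
                f"{len(self.spot_ids)} spot ids for {n} matrix rows"
            )
        if np.any(self.counts < 0):
            raise FormatError("negative counts present")
        if not np.all(np.isfinite(self.coords)):
            raise StructuralError("non-finite coordinates present")
        if len(np.unique(self.coords, axis=0)) != n:
            raise StructuralError("duplicate spot coordinates present")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Total UMI count per spot."""
        return self.counts.sum(axis=1)


@dataclass
class NormalizedExpression:
    """Library-size-normalized, Anscombe-stabilized expression values."""

    values: np.ndarray
    coords: np.ndarray
    gene_names: list[str]
    spot_ids: list[str]
    normalization_meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise StructuralError("non-finite normalized values")
        if np.any(self.values < 0):
            raise StructuralError("negative normalized values")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


def _parse_spot_token(token: str) -> tuple[float, float]:
    parts = str(token).split("x")
    if len(parts) != 2:
        raise ParseError(f"spot id {token!r} is not of the form '<x1>x<x2>'")
    try:
        return float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise ParseError(f"spot id {token!r}: non-numeric coordinate") from exc


def _read_coord_table(path: Path, spot_ids: Sequence[str]) -> np.ndarray:
    tab = pd.read_csv(path, sep="\t", dtype={0: str})
    if tab.shape[1] < 3:
        raise StructuralError(
            f"coordinate table {path} needs columns (spot_id, x1, x2)"
        )
    tab = tab.set_index(tab.columns[0])
    missing = [s for s in spot_ids if s not in tab.index]
    if missing:
        raise StructuralError(
            f"coordinate table {path} missing {len(missing)} spot ids "
            f"(first: {missing[0]!r})"
        )
    return tab.loc[list(spot_ids)].iloc[:, :2].to_numpy(dtype=float)


def read_counts(
    path: str | Path,
    fmt: str = "dense-tsv",
    *,
    coords_path: str | Path | None = None,
    genes_path: str | Path | None = None,
    spots_path: str | Path | None = None,
) -> SpatialCountMatrix:
    """Read a spot x gene count matrix from disk.

    Parameters
    ----------
    path
        Count matrix file. For ``fmt="dense-tsv"``, a tab-separated matrix
        with spots as rows; for ``fmt="mtx-triplet"``, a MatrixMarket file.
    fmt
        ``"dense-tsv"`` or ``"mtx-triplet"``.
    coords_path
        Coordinate table (spot_id, x1, x2). Optional for dense TSV whose spot
        ids encode coordinates; required for MatrixMarket input.
    genes_path, spots_path
        Sidecar files for MatrixMarket input (one identifier per line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "dense-tsv":
        return _read_dense_tsv(path, coords_path)
    if fmt == "mtx-triplet":
        if coords_path is None or genes_path is None or spots_path is None:
            raise StructuralError(
                "mtx-triplet input requires coords_path, genes_path and spots_path"
            )
        return _read_mtx(path, Path(coords_path), Path(genes_path), Path(spots_path))
    raise ValueError(f"unknown format {fmt!r}")


def _read_dense_tsv(path: Path, coords_path: str | Path | None) -> SpatialCountMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise StructuralError(f"{path}: empty file") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise StructuralError(f"{path}: no spots or no genes in matrix")
    spot_ids = [str(s) for s in df.index]
    gene_names = [str(g) for g in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric count entry") from exc
    if not np.all(np.isfinite(values)):
        raise FormatError(f"{path}: non-finite count entry")
    counts = values.astype(np.int64)
    if np.any(counts != values):
        bad = np.argwhere(counts != values)[0]
        raise FormatError(
            f"{path}: non-integer count at spot {spot_ids[bad[0]]!r}, "
            f"gene {gene_names[bad[1]]!r}"
        )
    if coords_path is not None:
        coords = _read_coord_table(Path(coords_path), spot_ids)
    else:
        coords = np.array([_parse_spot_token(s) for s in spot_ids], dtype=float)
    return SpatialCountMatrix(counts, coords, gene_names, spot_ids)


def _read_mtx(
    path: Path, coords_path: Path, genes_path: Path, spots_path: Path
) -> SpatialCountMatrix:
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    if not np.allclose(mat, np.round(mat)):
        raise FormatError(f"{path}: non-integer count entry")
    counts = np.round(mat).astype(np.int64)
    gene_names = Path(genes_path).read_text().split()
    spot_ids = Path(spots_path).read_text().split()
    if counts.shape != (len(spot_ids), len(gene_names)):
        raise StructuralError(
            f"matrix shape {counts.shape} does not match "
            f"{len(spot_ids)} spots x {len(gene_names)} genes"
        )
    coords = _read_coord_table(coords_path, spot_ids)
    return SpatialCountMatrix(counts, coords, gene_names, spot_ids)


def write_counts(
    data: SpatialCountMatrix,
    path: str | Path,
    coords_path: str | Path | None = None,
) -> None:
    """Write counts as dense TSV; optionally write a coordinate table too."""
    df = pd.DataFrame(data.counts, index=data.spot_ids, columns=data.gene_names)
    df.index.name = "spot_id"
    df.to_csv(path, sep="\t")
    if coords_path is not None:
        coord_df = pd.DataFrame(
            {"spot_id": data.spot_ids, "x1": data.coords[:, 0], "x2": data.coords[:, 1]}
        )
        coord_df.to_csv(coords_path, sep="\t", index=False)


def coordinate_spot_ids(coords: np.ndarray) -> list[str]:
    """Encode coordinates as "<x1>x<x2>" spot-identifier tokens."""
    return [f"{repr(float(a))}x{repr(float(b))}" for a, b in np.asarray(coords)]


def qc_filter(
    data: SpatialCountMatrix,
    min_total: int = 3,
    drop_prefixes: Sequence[str] = DEFAULT_DROP_PREFIXES,
) -> SpatialCountMatrix:
    """Drop spike-in/mitochondrial genes and practically unobservable genes.

    Genes whose name starts (case-insensitively) with any of ``drop_prefixes``
    are removed, as are genes with total count below ``min_total`` across all
    spots. Spots are never removed, and retained genes keep their order. The
    returned object's ``qc_log`` records each dropped gene and the reason.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    prefixes = tuple(p.upper() for p in drop_prefixes)
    totals = data.counts.sum(axis=0)
    reasons: list[tuple[str, str]] = []
    keep = np.ones(data.n_genes, dtype=bool)
    for j, name in enumerate(data.gene_names):
        upper = name.upper()
        hit = next((p for p in prefixes if upper.startswith(p)), None)
        if hit is not None:
            keep[j] = False
            reasons.append((name, f"prefix:{hit}"))
        elif totals[j] < min_total:
            keep[j] = False
            reasons.append((name, f"total_count<{min_total}"))
    if not keep.any():
        raise DegenerateOutputError("QC filtering removed every gene")
    log = pd.DataFrame(reasons, columns=["gene", "reason_dropped"])
    return SpatialCountMatrix(
        counts=data.counts[:, keep],
        coords=data.coords,
        gene_names=[g for g, k in zip(data.gene_names, keep) if k],
        spot_ids=data.spot_ids,
        qc_log=log,
    )


def normalize_and_stabilize(data: SpatialCountMatrix) -> NormalizedExpression:
    """Library-size normalize then variance-stabilize UMI counts.

    Each count ``c_ij`` is rescaled so the spot's library size matches the
    median library size, then Anscombe-transformed:

        value_ij = 2 * sqrt(s_med * c_ij / s_i + 3/8)

    where ``s_i`` is spot i's library size and ``s_med`` the median library
    size over spots.
    """
    sizes = data.library_sizes().astype(float)
    zero = np.flatnonzero(sizes == 0)
    if zero.size:
        offenders = [data.spot_ids[i] for i in zero[:10]]
        raise StIOError(
            f"{zero.size} spot(s) have zero library size: {offenders}"
        )
    s_med = float(np.median(sizes))
    scaled = s_med * data.counts / sizes[:, None]
    values = 2.0 * np.sqrt(scaled + ANSCOMBE_OFFSET)
    meta = {
        "library_sizes": sizes,
        "scaling_constant": s_med,
        "scaling_target": "median",
        "anscombe_offset": ANSCOMBE_OFFSET,
    }
    return NormalizedExpression(
        values=values,
        coords=data.coords,
        gene_names=list(data.gene_names),
        spot_ids=list(data.spot_ids),
        normalization_meta=meta,
    )


def write_normalized(expr: NormalizedExpression, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, index=expr.spot_ids, columns=expr.gene_names)
    df.index.name = "spot_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_qc_report(data: SpatialCountMatrix, path: str | Path) -> None:
    log = data.qc_log if data.qc_log is not None else pd.DataFrame(
        columns=["gene", "reason_dropped"]
    )
    log.to_csv(path, sep="\t", index=False)
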