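"""Spot-level data model: QC, normalization, size factors, denoising, Moran's I.

The central container is :class:`SpotTable`, holding raw counts, coordinates,
per-spot size factors and a denoised expression matrix rescaled to [0, 1].
Everything downstream (pattern detection, the MRF prior, the count model)
reads from a SpotTable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "SpotTable",
    "create_state",
    "minmax_rescale",
    "morans_i",
    "morans_filter",
    "size_factors",
    "denoise",
    "spatial_knn_weights",
]


@dataclass
class SpotTable:
    """Quality-controlled spatial transcriptome.

    Parameters
    ----------
    spot_ids : array of str
        Unique spot identifiers (barcodes).
    coords : (S, 2) float array
        Spot centroids in platform units (x, y).
    counts : (G, S) int array
        Raw gene-by-spot counts after QC.
    gene_names : array of str
        Unique gene symbols, length G.
    denoised : (G, S) float array or None
        Denoised expression, min-max rescaled per gene to [0, 1].
    size_factors : (S,) float array or None
        Per-spot scale factors with median 1.
    qc_log : dict
        Record of the filtering applied at construction.
    """

    spot_ids: np.ndarray
    coords: np.ndarray
    counts: np.ndarray
    gene_names: np.ndarray
    denoised: Optional[np.ndarray] = None
    size_factors: Optional[np.ndarray] = None
    qc_log: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, names) -> np.ndarray:
        """Row indices for the given gene symbols; unknown symbol is fatal."""
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in names if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return np.asarray([lookup[g] for g in names], dtype=int)


def create_state(
    coords,
    counts,
    gene_names,
    spot_ids=None,
    min_gene_frac: float = 0.01,
    drop_empty_spots: bool = True,
) -> SpotTable:
    """Build a :class:`SpotTable`, removing low-quality genes and spots.

    Genes detected (count > 0) in fewer than ``min_gene_frac`` of spots are
    dropped first; spots left with zero total count are then dropped (one
    re-evaluation pass, genes first).
    """
    counts = np.asarray(counts)
    coords = np.asarray(coords, dtype=float)
    gene_names = np.asarray(gene_names, dtype=object)
    if counts.ndim != 2:
        raise ValueError("counts must be 2-D (genes x spots)")
    G, S = counts.shape
    if len(gene_names) != G:
        raise ValueError(f"{len(gene_names)} gene names for {G} rows")
    if coords.shape != (S, 2):
        raise ValueError(f"coords shape {coords.shape} != ({S}, 2)")
    if len(set(gene_names)) != G:
        raise ValueError("duplicate gene names")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    counts = counts.astype(np.int64)
    if spot_ids is None:
        spot_ids = np.array([f"spot_{k}" for k in range(S)], dtype=object)
    else:
        spot_ids = np.asarray(spot_ids, dtype=object)

    detected = (counts > 0).sum(axis=1)
    gene_keep = detected >= min_gene_frac * S
    counts_f = counts[gene_keep]
    spot_keep = counts_f.sum(axis=0) > 0 if drop_empty_spots else np.ones(S, bool)
    counts_f = counts_f[:, spot_keep]
    if counts_f.size == 0 or counts_f.shape[0] == 0 or counts_f.shape[1] == 0:
        raise ValueError(
            f"empty matrix after QC: kept {int(gene_keep.sum())}/{G} genes, "
            f"{int(spot_keep.sum())}/{S} spots (min_gene_frac={min_gene_frac})"
        )
    qc_log = {
        "genes_in": int(G),
        "spots_in": int(S),
        "genes_removed": int(G - gene_keep.sum()),
        "spots_removed": int(S - spot_keep.sum()),
        "min_gene_frac": float(min_gene_frac),
    }
    return SpotTable(
        spot_ids=spot_ids[spot_keep],
        coords=coords[spot_keep],
        counts=counts_f,
        gene_names=gene_names[gene_keep],
        qc_log=qc_log,
    )


def minmax_rescale(matrix: np.ndarray) -> np.ndarray:
    """Per-row min-max rescaling to [0, 1]; constant rows map to zeros."""
    x = np.asarray(matrix, dtype=float)
    lo = x.min(axis=-1, keepdims=True)
    hi = x.max(axis=-1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(x)
    np.divide(x - lo, span, out=out, where=span > 0)
    return out


def spatial_knn_weights(coords, k: int = 6) -> sparse.csr_matrix:
    """Symmetric binary k-nearest-neighbor weight matrix, zero diagonal."""
    coords = np.asarray(coords, dtype=float)
    S = len(coords)
    if k >= S:
        raise ValueError(f"k={k} >= number of spots {S}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    graph = nn.kneighbors_graph(coords, mode="connectivity")
    graph.setdiag(0)
    graph.eliminate_zeros()
    w = graph.maximum(graph.T)  # symmetrize by union
    return w.tocsr()


def morans_i(values, weights) -> float:
    """Moran's I spatial autocorrelation statistic.

    I = (S / W) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z centered values
    and W the total weight. Constant input returns NaN.
    """
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0.0:
        return float("nan")
    w = sparse.csr_matrix(weights)
    W = w.sum()
    num = float(z @ (w @ z))
    return len(z) / W * num / denom


def morans_filter(matrix, weights, top_frac: float = 0.35, always_keep=None):
    """Indices of the top fraction of rows ranked by Moran's I.

    NaN scores (constant genes) rank last. ``always_keep`` row indices are
    force-included (used to protect marker genes).
    """
    matrix = np.asarray(matrix, dtype=float)
    scores = np.array([morans_i(row, weights) for row in matrix])
    order = np.argsort(np.where(np.isnan(scores), -np.inf, scores))[::-1]
    n_keep = max(1, int(np.ceil(top_frac * len(scores))))
    keep = set(order[:n_keep].tolist())
    if always_keep is not None:
        keep.update(int(i) for i in always_keep)
    idx = np.array(sorted(keep), dtype=int)
    return idx, scores


def size_factors(counts, method: str = "library-ratio") -> np.ndarray:
    """Per-spot size factors with median exactly 1.

    The default divides each spot's library size by the median library size.
    ``method`` may also be a callable ``counts -> (S,) positive array``.
    """
    counts = np.asarray(counts)
    if callable(method):
        sf = np.asarray(method(counts), dtype=float)
    elif method == "library-ratio":
        lib = counts.sum(axis=0).astype(float)
        if np.any(lib <= 0):
            raise ValueError("zero library size; run QC first")
        sf = lib / np.median(lib)
    else:
        raise ValueError(f"unknown size-factor method: {method!r}")
    if sf.shape != (counts.shape[1],) or np.any(sf <= 0):
        raise ValueError("size factors must be positive, one per spot")
    return sf / np.median(sf)


def _log_normalize(counts, sf):
    return np.log1p(np.asarray(counts, dtype=float) / sf[None, :])


def denoise(
    counts,
    coords=None,
    sf=None,
    method: str | Callable = "knn-smooth",
    k: int = 6,
    rescale: bool = True,
) -> np.ndarray:
    """Denoised expression matrix in [0, 1] (after per-gene min-max).

    The built-in ``"knn-smooth"`` method averages each spot's log-normalized
    expression over itself and its ``k`` spatial nearest neighbors, then
    inverts the log. Any callable ``counts -> non-negative (G, S) array``
    can be plugged in instead (e.g. an external denoiser).
    """
    counts = np.asarray(counts)
    G, S = counts.shape
    if callable(method):
        den = np.asarray(method(counts), dtype=float)
        if den.shape != counts.shape:
            raise ValueError(f"denoiser returned shape {den.shape}, expected {counts.shape}")
        if np.any(den < 0):
            raise ValueError("denoiser returned negative values")
    elif method == "knn-smooth":
        if sf is None:
            sf = size_factors(counts)
        logn = _log_normalize(counts, sf)
        if k == 0 or coords is None:
            smooth = logn
        else:
            nn = NearestNeighbors(n_neighbors=min(k + 1, S)).fit(coords)
            _, idx = nn.kneighbors(coords)
            smooth = logn[:, idx].mean(axis=2)
        den = np.expm1(smooth)
    else:
        raise ValueError(f"unknown denoise method: {method!r}")
    return minmax_rescale(den) if rescale else den
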