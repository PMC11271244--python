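"""High-order Markov-random-field prior over spot labels.

Each spot's label prior combines (i) a unary term from label frequencies in
its transcriptomic and spatial neighborhoods, and (ii) a pairwise term that
weights the global label co-occurrence rate by a feature-similarity penalty:
assigning different labels to look-alike neighbors costs ~2, the same label
costs ~1. Both terms are min-max scaled to [0, 1], combined with weight
omega2, and passed through a Gibbs/Boltzmann softmax with scale kappa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "NeighborGraph",
    "MRFHyper",
    "PriorField",
    "pca_embedding",
    "build_neighborhoods",
    "pairwise_penalty",
    "unary_term",
    "cooccurrence_rates",
    "pairwise_term",
    "energy_and_prior",
    "build_prior",
]


@dataclass
class NeighborGraph:
    """Transcriptomic (N_U) and spatial (N_S) neighbor lists per spot."""

    transcriptomic: List[np.ndarray]  # N_U(s), |.| = K
    spatial: List[np.ndarray]         # N_S(s)

    def union(self, s: int) -> np.ndarray:
        return np.union1d(self.transcriptomic[s], self.spatial[s])


@dataclass
class MRFHyper:
    """Hyperparameters of the prior.

    omega1 weights transcriptomic vs spatial neighborhood frequencies in the
    unary term; omega2 weights the pairwise vs unary energy; kappa scales
    the Gibbs distribution (larger = sharper prior); eps smooths empty
    frequencies. The recommended operating point is omega1=0.99,
    omega2=0.01 (initialization default 0.5/0.5).
    """

    omega1: float = 0.5
    omega2: float = 0.5
    kappa: float = 3.0
    eps: float = 1e-2
    sign: int = -1  # -1: Boltzmann e^{-kappa E}; +1 matches the printed form


@dataclass
class PriorField:
    cooccurrence: np.ndarray  # (R, R) joint label-pair frequencies, sums to 1
    energy: np.ndarray        # (S, R) in [0, 1]
    prior: np.ndarray         # (S, R) rows on the simplex
    unary: np.ndarray
    pairwise: np.ndarray


def pca_embedding(matrix, n_components: int = 50) -> np.ndarray:
    """Deterministic PCA scores (full SVD, sign-fixed), spots as rows."""
    X = np.asarray(matrix, dtype=float).T  # (S, G)
    X = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(s))
    # sign convention: largest-magnitude loading positive
    for c in range(k):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            U[:, c] *= -1
    return U[:, :k] * s[:k]


def _knn_lists(points, k: int) -> List[np.ndarray]:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    _, idx = nn.kneighbors(points)
    out = []
    for s in range(len(points)):
        row = idx[s][idx[s] != s][:k]
        out.append(np.asarray(row, dtype=int))
    return out


def build_neighborhoods(
    denoised,
    coords,
    K: int = 6,
    spatial_k: int = 6,
    embedding: Optional[Callable] = None,
    symmetrize: str = "none",
) -> NeighborGraph:
    """K-NN in an expression embedding plus spatial k-NN.

    The embedding is pluggable (e.g. UMAP); the default is deterministic
    50-component PCA of the denoised matrix. ``symmetrize`` applies to the
    spatial graph: "none" (directed k-NN), "union", or "mutual".
    """
    coords = np.asarray(coords, dtype=float)
    S = len(coords)
    if K >= S:
        raise ValueError(f"K={K} >= number of spots {S}")
    emb = embedding(denoised) if embedding is not None else pca_embedding(denoised)
    n_u = _knn_lists(np.asarray(emb, dtype=float), K)
    n_s = _knn_lists(coords, min(spatial_k, S - 1))
    if symmetrize != "none":
        sets = [set(a.tolist()) for a in n_s]
        out = []
        for s in range(S):
            if symmetrize == "union":
                nb = sets[s] | {t for t in range(S) if s in sets[t]}
            elif symmetrize == "mutual":
                nb = {t for t in sets[s] if s in sets[t]}
            else:
                raise ValueError(f"unknown symmetrize rule: {symmetrize!r}")
            out.append(np.asarray(sorted(nb), dtype=int))
        n_s = out
    return NeighborGraph(transcriptomic=n_u, spatial=n_s)


def pairwise_penalty(f_a, f_b, same_label: bool) -> float:
    """Feature-similarity penalty between two neighboring spots.

    With d the Euclidean feature distance: e^d for same-label pairs,
    1 + e^{-d} for different-label pairs. At d = 0 a same-label pair costs
    1 and a different-label pair costs 2.
    """
    d = float(np.linalg.norm(np.asarray(f_a, dtype=float) - np.asarray(f_b, dtype=float)))
    return float(np.exp(d)) if same_label else float(1.0 + np.exp(-d))


def unary_term(labels, graph: NeighborGraph, R: int, omega1: float = 0.5,
               eps: float = 1e-2) -> np.ndarray:
    """Unary energy Phi(l_s = r) from smoothed neighborhood label frequencies.

    Phi = -[w1 ln p_U + (1-w1) ln p_S], p = (count + eps) / (|N| + eps R).
    """
    labels = np.asarray(labels, dtype=int)
    S = len(labels)
    phi = np.zeros((S, R), dtype=float)
    for s in range(S):
        parts = []
        for nb in (graph.transcriptomic[s], graph.spatial[s]):
            cnt = np.bincount(labels[nb], minlength=R)[:R].astype(float)
            parts.append((cnt + eps) / (len(nb) + eps * R))
        with np.errstate(divide="ignore"):  # eps=0 callers accept -log 0
            phi[s] = -(omega1 * np.log(parts[0]) + (1.0 - omega1) * np.log(parts[1]))
    return phi


def cooccurrence_rates(labels, graph: NeighborGraph, R: int, eps: float = 1e-2) -> np.ndarray:
    """Joint distribution of ordered neighbor label pairs, eps-smoothed."""
    labels = np.asarray(labels, dtype=int)
    tally = np.zeros((R, R), dtype=float)
    for s in range(len(labels)):
        for t in graph.union(s):
            tally[labels[s], labels[t]] += 1.0
    tally += eps
    return tally / tally.sum()


def pairwise_term(labels, features, graph: NeighborGraph, cooc: np.ndarray) -> np.ndarray:
    """Pairwise energy Psi summed over each spot's neighborhood.

    Psi_sr = sum_{s' in N(s)} D(f_s, f_s'; r == l_s') * (-ln p_{r, l_s'}).
    """
    labels = np.asarray(labels, dtype=int)
    F = np.asarray(features, dtype=float)
    S, R = len(labels), cooc.shape[0]
    neg_log_p = -np.log(cooc)
    psi = np.zeros((S, R), dtype=float)
    for s in range(S):
        nb = graph.union(s)
        if len(nb) == 0:
            continue
        d = np.linalg.norm(F[nb] - F[s], axis=1)
        lab_nb = labels[nb]
        d_same = np.exp(d)          # penalty if r == l_{s'}
        d_diff = 1.0 + np.exp(-d)   # penalty otherwise
        for r in range(R):
            same = lab_nb == r
            pen = np.where(same, d_same, d_diff)
            psi[s, r] = float(np.sum(pen * neg_log_p[r, lab_nb]))
    return psi


def _minmax_table(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi > lo:
        return (x - lo) / (hi - lo)
    return np.zeros_like(x)


def energy_and_prior(phi, psi, omega2: float = 0.5, kappa: float = 3.0, sign: int = -1):
    """Combine unary/pairwise energies and form the Gibbs prior.

    Each component is min-max scaled over the whole (spot, pattern) table
    to [0, 1] before the weighted sum E = (1-w2) Phi + w2 Psi. The prior is
    a softmax of sign * kappa * E per spot; the default sign -1 gives lower
    energy -> higher prior (Boltzmann convention).
    """
    phi_n = _minmax_table(np.asarray(phi, dtype=float))
    psi_n = _minmax_table(np.asarray(psi, dtype=float))
    E = (1.0 - omega2) * phi_n + omega2 * psi_n
    z = sign * kappa * E
    z = z - z.max(axis=1, keepdims=True)
    expz = np.exp(z)
    pi = expz / expz.sum(axis=1, keepdims=True)
    return E, pi


def build_prior(labels, features, graph: NeighborGraph, R: int,
                hyper: Optional[MRFHyper] = None) -> PriorField:
    """Full prior construction from an annotation and its feature vectors."""
    hyper = hyper or MRFHyper()
    phi = unary_term(labels, graph, R, omega1=hyper.omega1, eps=hyper.eps)
    cooc = cooccurrence_rates(labels, graph, R, eps=hyper.eps)
    psi = pairwise_term(labels, features, graph, cooc)
    E, pi = energy_and_prior(phi, psi, omega2=hyper.omega2, kappa=hyper.kappa,
                             sign=hyper.sign)
    return PriorField(cooccurrence=cooc, energy=E, prior=pi, unary=phi, pairwise=psi)
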