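"""Synthetic spatial transcriptomes with known ground truth.

Spots sit on a regular grid partitioned into R patterns by one of three
layouts (laminar bands, concentric rings, dispersed Voronoi foci). Each
pattern overexpresses its marker genes by a fold factor delta on top of a
per-gene baseline, and counts are drawn from a negative binomial with
per-spot size factors — the same observation model the EM stage assumes —
so every downstream stage can be tested against truth without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple, Union

import numpy as np

__all__ = ["SimulationConfig", "SimulationResult", "simulate", "add_marker_noise"]


@dataclass
class SimulationConfig:
    """Study conditions of the generator.

    delta_true is the marker overexpression fold (> 1); a (lo, hi) tuple
    draws one fold per marker uniformly. alpha_true is the NB inverse
    dispersion; baseline_mean the per-gene baseline scale; libsize_sigma
    the log-sd of the spot size factors; dropout a Bernoulli zeroing rate.
    """

    shape: Tuple[int, int] = (40, 40)
    layout: str = "layered-bands"
    n_patterns: int = 4
    n_genes: int = 200
    markers_per_pattern: int = 3
    delta_true: Union[float, Tuple[float, float]] = 4.0
    alpha_true: float = 10.0
    baseline_mean: float = 1.0
    baseline_log_sd: float = 0.3
    libsize_sigma: float = 0.2
    dropout: float = 0.0
    seed: int = 0

    def validate(self):
        if self.markers_per_pattern * self.n_patterns > self.n_genes:
            raise ValueError("markers_per_pattern * n_patterns exceeds n_genes")
        if self.n_patterns < 1 or self.n_genes < 1:
            raise ValueError("need at least one pattern and one gene")
        return self


@dataclass
class SimulationResult:
    coords: np.ndarray          # (S, 2) float (x, y)
    counts: np.ndarray          # (G, S) int
    labels: np.ndarray          # (S,) int ground truth
    markers: Dict[str, List[str]]
    gene_names: np.ndarray
    pattern_names: List[str]
    sigma: np.ndarray           # (S,) true size factors
    baseline: np.ndarray        # (G,) true per-gene baseline
    anchor: np.ndarray          # (G, R) true beta_gr
    rho: np.ndarray             # (G, R) marker indicators
    delta: np.ndarray           # (G, R) true overexpression folds (1 where rho=0)
    noise_markers: Dict[str, List[str]] = field(default_factory=dict)


def _layout_labels(shape, layout: str, R: int, rng) -> np.ndarray:
    I, J = shape
    ii, jj = np.meshgrid(np.arange(I), np.arange(J), indexing="ij")
    if layout == "layered-bands":
        lab = (ii * R) // I
    elif layout == "concentric":
        ci, cj = (I - 1) / 2.0, (J - 1) / 2.0
        d = np.hypot(ii - ci, jj - cj).ravel()
        edges = np.quantile(d, np.linspace(0, 1, R + 1)[1:-1])
        lab = np.searchsorted(edges, d, side="right").reshape(I, J)
    elif layout == "dispersed-foci":
        n_foci = 3 * R
        centers = np.stack([rng.uniform(0, I, n_foci), rng.uniform(0, J, n_foci)], axis=1)
        pat = np.arange(n_foci) % R
        pts = np.stack([ii.ravel(), jj.ravel()], axis=1).astype(float)
        d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
        lab = pat[np.argmin(d, axis=1)].reshape(I, J)
    else:
        raise ValueError(f"unknown layout: {layout!r}")
    return lab.ravel().astype(int)


def simulate(config: SimulationConfig) -> SimulationResult:
    """Draw a synthetic tissue under the configured conditions."""
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    I, J = cfg.shape
    ii, jj = np.meshgrid(np.arange(I), np.arange(J), indexing="ij")
    coords = np.stack([jj.ravel().astype(float), ii.ravel().astype(float)], axis=1)  # (x, y)
    S = I * J
    R, G = cfg.n_patterns, cfg.n_genes
    labels = _layout_labels(cfg.shape, cfg.layout, R, rng)

    gene_names = np.array([f"G{g:04d}" for g in range(G)], dtype=object)
    pattern_names = [f"pattern_{r}" for r in range(R)]
    marker_idx = rng.choice(G, size=R * cfg.markers_per_pattern, replace=False)
    rho = np.zeros((G, R))
    markers: Dict[str, List[str]] = {}
    for r in range(R):
        rows = marker_idx[r * cfg.markers_per_pattern:(r + 1) * cfg.markers_per_pattern]
        rho[rows, r] = 1.0
        markers[pattern_names[r]] = [str(gene_names[g]) for g in rows]

    baseline = cfg.baseline_mean * rng.lognormal(0.0, cfg.baseline_log_sd, size=G)
    anchor = np.tile(baseline[:, None], (1, R))  # beta_gr scale = gene baseline
    if np.isscalar(cfg.delta_true):
        folds = np.full(int(rho.sum()), float(cfg.delta_true))
    else:
        lo, hi = cfg.delta_true
        folds = rng.uniform(lo, hi, size=int(rho.sum()))
    delta = np.ones((G, R))
    delta[rho > 0] = folds

    sigma = rng.lognormal(0.0, cfg.libsize_sigma, size=S)
    sigma = sigma / np.median(sigma)

    # mu_gs under each spot's true pattern: baseline + anchor * rho * delta
    mu = baseline[:, None] + (anchor * rho * delta)[:, labels]
    m = sigma[None, :] * mu
    p = cfg.alpha_true / (cfg.alpha_true + m)
    counts = rng.negative_binomial(cfg.alpha_true, p)
    if cfg.dropout > 0:
        counts = np.where(rng.random(counts.shape) < cfg.dropout, 0, counts)

    return SimulationResult(
        coords=coords, counts=counts.astype(np.int64), labels=labels,
        markers=markers, gene_names=gene_names, pattern_names=pattern_names,
        sigma=sigma, baseline=baseline, anchor=anchor, rho=rho, delta=delta,
    )


def add_marker_noise(markers: Dict[str, List[str]], n_noise: int, gene_pool,
                     seed: int = 0):
    """Append non-informative genes to each pattern's marker list.

    The pool must be disjoint from the true markers; draws are without
    replacement across patterns. Returns the noised list and a record of
    which genes are noise.
    """
    pool = [str(g) for g in gene_pool]
    used = {g for genes in markers.values() for g in genes}
    overlap = used & set(pool)
    if overlap:
        raise ValueError(f"pool overlaps true markers: {sorted(overlap)[:5]}")
    need = n_noise * len(markers)
    if need > len(pool):
        raise ValueError(f"pool of {len(pool)} cannot supply {need} noise genes")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(pool), size=need, replace=False)
    out = {p: list(g) for p, g in markers.items()}
    record: Dict[str, List[str]] = {}
    for k, pat in enumerate(markers):
        chosen = [pool[i] for i in picks[k * n_noise:(k + 1) * n_noise]]
        out[pat].extend(chosen)
        record[pat] = chosen
    return out, record
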