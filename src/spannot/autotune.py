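"""Detector hyperparameter search and marker-list expansion.

The search objective scores an annotation by how specifically each pattern's
initial markers light up in the spots assigned to that pattern: the
row-normalized mean-expression table should look like the identity matrix,
and the Frobenius distance to it is minimized over detector parameter sets.
Candidate markers are then ranked per pattern with a one-vs-rest Wilcoxon
rank-sum test on log-normalized counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .detector import DetectorParams, detect

__all__ = [
    "SearchSpace",
    "TrialResult",
    "specificity_matrix",
    "objective",
    "search",
    "rank_candidate_markers",
    "rank_sum_z",
    "expand_markers",
]


@dataclass
class SearchSpace:
    """Named parameter domains over DetectorParams.

    ``domains`` maps a DetectorParams field to either ``{"choice": [...]}``
    or ``{"range": [lo, hi]}`` (uniform float).
    """

    domains: Dict[str, dict]
    budget: int = 20
    seed: int = 0

    def sample(self, rng: np.random.Generator, base: DetectorParams) -> DetectorParams:
        kwargs = {}
        for name, dom in self.domains.items():
            if "choice" in dom:
                opts = dom["choice"]
                kwargs[name] = opts[rng.integers(len(opts))]
            elif "range" in dom:
                lo, hi = dom["range"]
                kwargs[name] = float(rng.uniform(lo, hi))
            else:
                raise ValueError(f"domain for {name!r} needs 'choice' or 'range'")
        return replace(base, **kwargs)


@dataclass
class TrialResult:
    params: DetectorParams
    score: float
    error: Optional[str] = None


def specificity_matrix(expression, labels, markers: Dict[str, list], gene_index,
                       pattern_names: List[str]):
    """R x R specificity of initial markers on an annotation.

    Entry (r, r') is the mean expression of pattern r's markers among spots
    labeled r', min-max normalized within each row. Patterns with no
    assigned spots contribute zero columns; the count of such empty
    patterns is returned for the objective's penalty.
    """
    expression = np.asarray(expression, dtype=float)
    labels = np.asarray(labels, dtype=int)
    R = len(pattern_names)
    raw = np.zeros((R, R), dtype=float)
    n_empty = 0
    for rp in range(R):
        sel = labels == rp
        if not sel.any():
            n_empty += 1
            continue
        for r, pat in enumerate(pattern_names):
            genes = markers.get(pat, [])
            if not genes:
                continue
            rows = gene_index(genes)
            raw[r, rp] = expression[np.asarray(rows)][:, sel].mean()
    lo = raw.min(axis=1, keepdims=True)
    hi = raw.max(axis=1, keepdims=True)
    span = hi - lo
    T = np.zeros_like(raw)
    np.divide(raw - lo, span, out=T, where=span > 0)
    return T, n_empty


def objective(T, n_empty: int = 0) -> float:
    """Frobenius distance of the specificity matrix to the identity.

    Each pattern the annotation failed to assign any spot adds a penalty
    of 1, since the distance is undefined on a vanished pattern.
    """
    T = np.asarray(T, dtype=float)
    R = T.shape[0]
    return float(np.linalg.norm(T - np.eye(R))) + float(n_empty)


def search(space: SearchSpace, state, markers: Dict[str, list],
           base_params: Optional[DetectorParams] = None, use_raw: bool = False):
    """Seeded random search over detector parameters.

    Each trial runs the full detector and scores the resulting annotation;
    the lowest objective wins, first-evaluated winning ties. Returns
    (best params, best annotation, trial log).
    """
    base = base_params or DetectorParams()
    rng = np.random.default_rng(space.seed)
    named = {p: g for p, g in markers.items() if g}
    names = list(named.keys())
    expr = state.counts.astype(float) if use_raw else state.denoised
    best: Optional[TrialResult] = None
    best_ann = None
    log: List[TrialResult] = []
    for _ in range(space.budget):
        params = space.sample(rng, base)
        try:
            ann = detect(state, markers, params=params)
            T, n_empty = specificity_matrix(expr, ann.labels, named,
                                            state.gene_index, names)
            score = objective(T, n_empty)
            trial = TrialResult(params=params, score=score)
        except (ValueError, FloatingPointError) as exc:
            trial = TrialResult(params=params, score=np.inf, error=str(exc))
            ann = None
        log.append(trial)
        if np.isfinite(trial.score) and (best is None or trial.score < best.score):
            best, best_ann = trial, ann
    if best is None:
        msgs = "; ".join(t.error or "?" for t in log)
        raise RuntimeError(f"all {space.budget} trials failed: {msgs}")
    return best.params, best_ann, log


def rank_sum_z(values, in_group):
    """Tie-corrected two-sample Wilcoxon rank-sum z (normal approximation).

    ``values``: (G, S) matrix; ``in_group``: boolean (S,). Returns z per
    gene, positive when the group ranks higher than the rest.
    """
    values = np.asarray(values, dtype=float)
    in_group = np.asarray(in_group, dtype=bool)
    n1 = int(in_group.sum())
    n = values.shape[1]
    n2 = n - n1
    ranks = stats.rankdata(values, axis=1)
    w = ranks[:, in_group].sum(axis=1)
    mean_w = n1 * (n + 1) / 2.0
    # tie correction to the rank-sum variance
    var = np.empty(values.shape[0])
    base_var = n1 * n2 * (n + 1) / 12.0
    for g in range(values.shape[0]):
        _, counts = np.unique(values[g], return_counts=True)
        tie = (counts**3 - counts).sum()
        var[g] = base_var - n1 * n2 * tie / (12.0 * n * (n - 1))
    z = np.zeros(values.shape[0])
    ok = var > 0
    z[ok] = (w[ok] - mean_w) / np.sqrt(var[ok])
    return z


def rank_candidate_markers(counts, labels, pattern_names, sf=None, top_k: int = 10):
    """Per-pattern candidate markers by one-vs-rest rank-sum on log counts.

    Returns a DataFrame with columns pattern, gene (row index), z, p, rank.
    Patterns with fewer than 2 spots are skipped.
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two labels for differential ranking")
    if sf is None:
        sf = np.ones(counts.shape[1])
    logn = np.log1p(counts / np.asarray(sf)[None, :])
    records = []
    for r, pat in enumerate(pattern_names):
        sel = labels == r
        if sel.sum() < 2 or (~sel).sum() < 2:
            continue
        z = rank_sum_z(logn, sel)
        p = 2.0 * stats.norm.sf(np.abs(z))
        order = np.argsort(-z)[:top_k]
        for rank, g in enumerate(order, start=1):
            records.append({"pattern": pat, "gene": int(g), "z": float(z[g]),
                            "p": float(p[g]), "rank": rank})
    return pd.DataFrame.from_records(records)


def expand_markers(markers: Dict[str, list], candidates: pd.DataFrame,
                   gene_names, per_pattern: int = 3) -> Dict[str, list]:
    """Append top-ranked candidate genes to each pattern's marker list.

    A gene already claimed (initial marker anywhere, or a higher-z candidate
    of another pattern) is skipped, so expanded lists stay disjoint.
    """
    gene_names = np.asarray(gene_names, dtype=object)
    out = {p: list(g) for p, g in markers.items()}
    claimed = {g for genes in out.values() for g in genes}
    if len(candidates) == 0:
        return out
    for _, row in candidates.sort_values("z", ascending=False).iterrows():
        pat = row["pattern"]
        gene = str(gene_names[int(row["gene"])])
        if pat not in out or gene in claimed:
            continue
        added = len(out[pat]) - len(markers.get(pat, []))
        if added >= per_pattern:
            continue
        out[pat].append(gene)
        claimed.add(gene)
    return out
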