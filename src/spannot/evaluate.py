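"""Agreement metrics between predicted and reference annotations.

Cluster labels are first mapped to reference structures with the
Kuhn-Munkres (Hungarian) assignment on the contingency table; accuracy and
macro precision/recall/F1 are computed on the mapped labels, while ARI and
NMI are mapping-free. A column-normalized confusion matrix and the
Jensen-Shannon divergence between label frequency distributions round out
the suite.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import jensenshannon
from sklearn import metrics as skm

__all__ = [
    "contingency",
    "hungarian_map",
    "apply_mapping",
    "metrics",
    "confusion_by_column",
    "jsd",
    "assign_clusters_to_structures",
]

UNASSIGNED = -1


def _codes(labels):
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    return uniq, codes


def contingency(pred, truth) -> pd.DataFrame:
    """Overlap table: rows predicted clusters, columns true structures."""
    pu, pc = _codes(pred)
    tu, tc = _codes(truth)
    tab = np.zeros((len(pu), len(tu)), dtype=int)
    np.add.at(tab, (pc, tc), 1)
    return pd.DataFrame(tab, index=pu, columns=tu)


def hungarian_map(pred, truth) -> Dict:
    """Injective cluster-to-structure assignment maximizing matched spots.

    Extra clusters beyond the number of structures map to ``UNASSIGNED``.
    """
    tab = contingency(pred, truth)
    cost = -tab.to_numpy(dtype=float)
    ri, ci = linear_sum_assignment(cost)
    mapping = {c: UNASSIGNED for c in tab.index}
    for r, c in zip(ri, ci):
        mapping[tab.index[r]] = tab.columns[c]
    return mapping


def apply_mapping(pred, mapping):
    return np.asarray([mapping.get(p, UNASSIGNED) for p in np.asarray(pred)], dtype=object)


def metrics(pred, truth, exclude=None) -> Dict[str, float]:
    """ARI, ACC, macro P/R/F1 and NMI between two labelings.

    ACC/P/R/F1 are computed after Hungarian mapping; macro averages run
    over the structures present in the truth. ``exclude`` lists truth
    labels (e.g. an unassigned/undefined class) whose spots are dropped
    before scoring. Single-class truth yields NaN ARI with a warning-free
    sentinel.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if exclude is not None:
        keep = ~np.isin(truth, list(exclude))
        pred, truth = pred[keep], truth[keep]
    classes = np.unique(truth)
    out: Dict[str, float] = {}
    out["ARI"] = float("nan") if len(classes) < 2 else float(
        skm.adjusted_rand_score(truth, pred))
    out["NMI"] = float(skm.normalized_mutual_info_score(truth, pred,
                                                        average_method="arithmetic"))
    mapping = hungarian_map(pred, truth)
    mapped = apply_mapping(pred, mapping)
    out["ACC"] = float(np.mean(mapped == truth))
    p, r, f1 = _macro_prf(mapped, truth, classes)
    out["P"], out["R"], out["F1"] = p, r, f1
    return out


def _macro_prf(mapped, truth, classes):
    ps, rs, fs = [], [], []
    for c in classes:
        tp = np.sum((mapped == c) & (truth == c))
        fp = np.sum((mapped == c) & (truth != c))
        fn = np.sum((mapped != c) & (truth == c))
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        ps.append(prec)
        rs.append(rec)
        fs.append(f1)
    return float(np.mean(ps)), float(np.mean(rs)), float(np.mean(fs))


def confusion_by_column(pred, truth, mapping: Optional[Dict] = None) -> pd.DataFrame:
    """Confusion matrix with each true-structure column normalized to 1.

    Rows are mapped predicted structures; the diagonal holds per-structure
    precision in the column-normalized sense.
    """
    if mapping is None:
        mapping = hungarian_map(pred, truth)
    mapped = apply_mapping(pred, mapping)
    classes = np.unique(np.asarray(truth))
    tab = np.zeros((len(classes), len(classes)), dtype=float)
    idx = {c: k for k, c in enumerate(classes)}
    for m, t in zip(mapped, np.asarray(truth)):
        if m in idx:
            tab[idx[m], idx[t]] += 1
    sums = tab.sum(axis=0, keepdims=True)
    np.divide(tab, sums, out=tab, where=sums > 0)
    return pd.DataFrame(tab, index=classes, columns=classes)


def jsd(freq_p, freq_q) -> float:
    """Base-2 Jensen-Shannon divergence between two frequency vectors.

    Inputs are normalized internally; the result lies in [0, 1], reaching 1
    only for disjoint supports.
    """
    p = np.asarray(freq_p, dtype=float)
    q = np.asarray(freq_q, dtype=float)
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("frequency vectors must have positive mass")
    return float(jensenshannon(p / p.sum(), q / q.sum(), base=2) ** 2)


def assign_clusters_to_structures(cluster_labels, structure_labels):
    """Map each cluster to the structure holding its largest spot share.

    Ties break toward the lexicographically lowest structure. Also returns
    the cluster-by-structure proportion table (rows sum to 1).
    """
    tab = contingency(cluster_labels, structure_labels)
    prop = tab.div(tab.sum(axis=1), axis=0)
    assignment = {c: prop.columns[int(np.argmax(prop.loc[c].to_numpy()))]
                  for c in prop.index}
    return assignment, prop
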