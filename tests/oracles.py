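"""Independent brute-force oracles used across the test suite.

Everything here is written from first principles (nested loops, exhaustive
enumeration, closed forms) and deliberately avoids the code paths under
test.
"""

import itertools
import math

import numpy as np


def morans_i_bruteforce(values, weights_dense):
    """O(S^2) double-sum Moran's I."""
    z = np.asarray(values, float) - np.mean(values)
    w = np.asarray(weights_dense, float)
    S = len(z)
    W = w.sum()
    num = 0.0
    for i in range(S):
        for j in range(S):
            num += w[i, j] * z[i] * z[j]
    return S / W * num / np.sum(z**2)


def multiotsu_variance(values, nbins, thresholds):
    """Between-class variance attained by the given thresholds (bin centers)."""
    values = np.asarray(values, float)
    hist, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    probs = hist / hist.sum()
    splits = np.searchsorted(centers, np.sort(thresholds), side="right") - 1
    bounds = [-1] + list(splits) + [nbins - 1]
    var = 0.0
    for k in range(len(bounds) - 1):
        sel = slice(bounds[k] + 1, bounds[k + 1] + 1)
        w = probs[sel].sum()
        if w > 0:
            mu = (probs[sel] * centers[sel]).sum() / w
            var += w * mu**2
    return var


def multiotsu_bruteforce(values, classes, nbins):
    """Exhaustive search over all threshold tuples on the histogram bins.

    Mirrors histogram-based Otsu: bin the values, then maximize the
    between-class variance over every ordered tuple of split bins; returns
    thresholds as bin centers, descending.
    """
    values = np.asarray(values, float)
    hist, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    probs = hist / hist.sum()
    best, best_idx = -np.inf, None
    idx_range = range(nbins - 1)
    for splits in itertools.combinations(idx_range, classes - 1):
        bounds = (-1,) + splits + (nbins - 1,)
        var = 0.0
        ok = True
        for k in range(classes):
            sel = slice(bounds[k] + 1, bounds[k + 1] + 1)
            w = probs[sel].sum()
            if w == 0:
                ok = False
                break
            mu = (probs[sel] * centers[sel]).sum() / w
            var += w * mu**2
        if ok and var > best:
            best, best_idx = var, splits
    return np.sort(centers[list(best_idx)])[::-1], best


def hungarian_bruteforce(table):
    """Best injective row->column assignment by enumerating permutations."""
    table = np.asarray(table)
    nr, nc = table.shape
    best, best_map = -1, None
    cols = list(range(nc))
    for perm in itertools.permutations(cols, min(nr, nc)):
        rows = list(range(nr))[: len(perm)]
        total = sum(table[r, c] for r, c in zip(rows, perm))
        if total > best:
            best = total
            best_map = dict(zip(rows, perm))
    return best_map, best


def contingency_bruteforce(pred, truth):
    pu = sorted(set(pred))
    tu = sorted(set(truth))
    tab = np.zeros((len(pu), len(tu)), dtype=int)
    for p, t in zip(pred, truth):
        tab[pu.index(p), tu.index(t)] += 1
    return tab, pu, tu


def ari_bruteforce(pred, truth):
    tab, _, _ = contingency_bruteforce(list(pred), list(truth))
    n = tab.sum()
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = sum(comb(v) for v in tab.ravel())
    a = sum(comb(v) for v in tab.sum(axis=1))
    b = sum(comb(v) for v in tab.sum(axis=0))
    expected = a * b / comb(n)
    max_idx = (a + b) / 2.0
    return (sum_ij - expected) / (max_idx - expected)


def nmi_bruteforce(pred, truth):
    """Mutual information over joint entropy-mean normalization."""
    tab, _, _ = contingency_bruteforce(list(pred), list(truth))
    n = tab.sum()
    pj = tab / n
    pr = pj.sum(axis=1)
    pc = pj.sum(axis=0)
    mi = 0.0
    for i in range(tab.shape[0]):
        for j in range(tab.shape[1]):
            if pj[i, j] > 0:
                mi += pj[i, j] * math.log(pj[i, j] / (pr[i] * pc[j]))
    h = lambda p: -sum(x * math.log(x) for x in p if x > 0)
    denom = (h(pr) + h(pc)) / 2.0
    return mi / denom if denom > 0 else 0.0


def macro_f1_bruteforce(mapped, truth):
    classes = sorted(set(truth))
    ps, rs, fs = [], [], []
    for c in classes:
        tp = sum(1 for m, t in zip(mapped, truth) if m == c and t == c)
        fp = sum(1 for m, t in zip(mapped, truth) if m == c and t != c)
        fn = sum(1 for m, t in zip(mapped, truth) if m != c and t == c)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        ps.append(p)
        rs.append(r)
        fs.append(f)
    return np.mean(ps), np.mean(rs), np.mean(fs)


def ranksum_z_bruteforce(x_group, x_rest):
    """Tie-corrected rank-sum z from scratch (ranks by hand)."""
    pooled = list(x_group) + list(x_rest)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    n1, n2 = len(x_group), len(x_rest)
    n = n1 + n2
    w = sum(ranks[:n1])
    mean_w = n1 * (n + 1) / 2.0
    # tie correction
    from collections import Counter

    tie = sum(c**3 - c for c in Counter(pooled).values())
    var = n1 * n2 * (n + 1) / 12.0 - n1 * n2 * tie / (12.0 * n * (n - 1))
    return (w - mean_w) / math.sqrt(var)


def flood_fill_components(binary):
    """8-connected component count by explicit flood fill."""
    binary = np.asarray(binary, bool)
    seen = np.zeros_like(binary)
    count = 0
    I, J = binary.shape
    for i0 in range(I):
        for j0 in range(J):
            if binary[i0, j0] and not seen[i0, j0]:
                count += 1
                stack = [(i0, j0)]
                seen[i0, j0] = True
                while stack:
                    i, j = stack.pop()
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = i + di, j + dj
                            if 0 <= ni < I and 0 <= nj < J and binary[ni, nj] \
                                    and not seen[ni, nj]:
                                seen[ni, nj] = True
                                stack.append((ni, nj))
    return count


def two_means_1d_bruteforce(values):
    """Exact 1-D 2-means by scanning every sorted split; returns hi-cluster mask."""
    v = np.asarray(values, float)
    order = np.argsort(v)
    sv = v[order]
    n = len(sv)
    best_cost, best_k = np.inf, None
    for k in range(1, n):
        lo, hi = sv[:k], sv[k:]
        cost = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if cost < best_cost - 1e-15:
            best_cost, best_k = cost, k
    mask = np.zeros(n, bool)
    if best_k is not None:
        mask[order[best_k:]] = True
    return mask


def jsd_bruteforce(p, q):
    p = np.asarray(p, float)
    p = p / p.sum()
    q = np.asarray(q, float)
    q = q / q.sum()
    m = (p + q) / 2.0
    kl = lambda a, b: sum(x * math.log2(x / y) for x, y in zip(a, b) if x > 0)
    return 0.5 * kl(p, m) + 0.5 * kl(q, m)
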