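"""Independent brute-force oracles used to cross-check the implementation.

Each routine here recomputes a quantity by direct enumeration or by a
second, deliberately naive formulation, independent of the library code
paths it validates.
"""

from itertools import combinations
from math import comb

import numpy as np


def brute_force_nearest_centroid(x, centroids, scale, class_labels):
    """Classify one sample by explicit per-class distance loops.

    x: (n_genes,), centroids: (k, n_genes), scale: (n_genes,) divisor
    (ones for plain Euclidean). Ties go to the earliest listed class.
    """
    best_label, best_d = None, None
    distances = []
    for label, c in zip(class_labels, centroids):
        d = 0.0
        for g in range(len(x)):
            d += ((x[g] - c[g]) / scale[g]) ** 2
        distances.append(d)
        if best_d is None or d < best_d:
            best_label, best_d = label, d
    return best_label, distances


def exact_wilcoxon_two_sided(x, y):
    """Two-sided rank-sum p by full enumeration of rank assignments.

    Valid for untied data. p = fraction of all C(n1+n2, n1) assignments of
    ranks to the first group whose rank sum is at least as extreme (in
    distance from its mean) as the observed one.
    """
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (len(pooled) + 1) / 2.0
    extreme = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            extreme += 1
        total += 1
    return extreme / total


def fisher_exact_two_sided(table):
    """Two-sided Fisher p by enumerating every table with the observed
    margins, summing probabilities <= that of the observed table."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


def hypergeom_upper_tail(k, N, K, n):
    """P(X >= k) by direct pmf summation."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += comb(K, x) * comb(N - K, n - x) / comb(N, n)
    return total


def pooled_t(x, y):
    """Hand-arithmetic two-sample pooled-variance t."""
    n1, n2 = len(x), len(y)
    m1, m2 = sum(x) / n1, sum(y) / n2
    ss1 = sum((v - m1) ** 2 for v in x)
    ss2 = sum((v - m2) ** 2 for v in y)
    sp = ((ss1 + ss2) / (n1 + n2 - 2)) ** 0.5
    return (m1 - m2) / (sp * (1 / n1 + 1 / n2) ** 0.5)


def km_product_limit(times, events):
    """Spreadsheet-style Kaplan-Meier: returns {event time: S(t)}."""
    order = np.argsort(times, kind="stable")
    times = np.asarray(times)[order]
    events = np.asarray(events)[order]
    s = 1.0
    out = {}
    n = len(times)
    for t in sorted(set(times[events.astype(bool)])):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & events.astype(bool)).sum())
        s *= 1.0 - d / at_risk
        out[t] = s
    return out


def normalize_reference(counts):
    """Second straightforward implementation of the normalization recipe:
    log2(1+x), per-sample UQ scaling over positive values, per-gene median
    centering. Loops on purpose."""
    counts = np.asarray(counts, dtype=float)
    v = np.log2(1.0 + counts)
    n_genes, n_samples = v.shape
    uqs = []
    for j in range(n_samples):
        pos = sorted(val for val in v[:, j] if val > 0)
        uqs.append(float(np.percentile(pos, 75)))
    target = sum(uqs) / len(uqs)
    scaled = np.empty_like(v)
    for j in range(n_samples):
        scaled[:, j] = v[:, j] * target / uqs[j]
    out = np.empty_like(scaled)
    for i in range(n_genes):
        out[i, :] = scaled[i, :] - np.median(scaled[i, :])
    return out
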