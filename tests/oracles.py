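"""Independent brute-force oracles shared by the unit and acceptance suites.

Deliberately naive: plain loops over every candidate split / every
positive-negative pair / the raw ANOVA mean-square formulas, kept separate
from the library code paths they check.
"""

import numpy as np


def otsu_bruteforce(values, n_bins=256):
    """Exhaustive search over all histogram split points."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    counts, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    total = counts.sum()
    best_k, best_bcv = None, -1.0
    for k in range(n_bins - 1):
        w0 = counts[: k + 1].sum()
        w1 = counts[k + 1 :].sum()
        if w0 == 0 or w1 == 0:
            bcv = 0.0
        else:
            mu0 = (counts[: k + 1] * np.arange(k + 1)).sum() / w0
            mu1 = (counts[k + 1 :] * np.arange(k + 1, n_bins)).sum() / w1
            bcv = w0 * w1 / total**2 * (mu0 - mu1) ** 2
        if bcv > best_bcv:
            best_bcv, best_k = bcv, k
    return float(edges[best_k + 1])


def auc_bruteforce(score, truth):
    """Pairwise wins + half ties over all positive/negative pairs."""
    score = np.asarray(score, dtype=float)
    truth = np.asarray(truth, dtype=int)
    pos = score[truth == 1]
    neg = score[truth == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def kappa_bruteforce(x, y):
    """Direct p_o / p_e evaluation over the observed categories."""
    x = np.asarray(x)
    y = np.asarray(y)
    cats = sorted(set(x) | set(y))
    n = len(x)
    p_o = sum(a == b for a, b in zip(x, y)) / n
    p_e = sum(
        (sum(x == c) / n) * (sum(y == c) / n) for c in cats
    )
    return (p_o - p_e) / (1 - p_e)


def icc_bruteforce(matrix):
    """ICC(2,1) and ICC(2,k) straight from the two-way ANOVA mean squares."""
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssb = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((m - grand) ** 2).sum()
    sse = sst - ssb - ssc
    msr = ssb / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    single = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    average = (msr - mse) / (msr + (msc - mse) / n)
    return single, average


def ccc_bruteforce(x, y):
    """Lin's concordance from explicitly evaluated population moments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    mx, my = x.sum() / n, y.sum() / n
    vx = sum((xi - mx) ** 2 for xi in x) / n
    vy = sum((yi - my) ** 2 for yi in y) / n
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / n
    return 2 * sxy / (vx + vy + (mx - my) ** 2)
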