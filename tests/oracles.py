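"""Independent brute-force oracles used by the test suite.

Each oracle is written in the most literal way possible (nested loops,
exhaustive enumeration) and deliberately shares no code with the package
implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def sampen_bruteforce(series, m: int, r: float) -> float:
    """Exhaustive Richman-Moorman sample entropy.

    Counts unordered pairs (i < j) of templates among the first N - m, for
    lengths m and m + 1, with Chebyshev distance <= r.  Returns -ln(A/B);
    0.0 for a constant series; raises ValueError when B or A is zero.
    """
    x = [float(v) for v in series]
    n = len(x)
    if len(set(x)) == 1:
        return 0.0
    n_templates = n - m
    b = 0
    a = 0
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    if b == 0 or a == 0:
        raise ValueError("no matching template pairs; SampEn undefined")
    return -math.log(a / b)


def knn_bruteforce(train_x, train_labels, test_x, k: int):
    """All-pairs Euclidean KNN on z-scored features.

    Standardization uses training mean/SD; majority vote, ties resolved in
    favor of the tied class owning the closest neighbor.
    """
    train_x = np.asarray(train_x, dtype=float)
    test_x = np.asarray(test_x, dtype=float)
    mu = train_x.mean(axis=0)
    sd = train_x.std(axis=0)
    sd[sd == 0] = 1.0
    train_z = (train_x - mu) / sd
    test_z = (test_x - mu) / sd

    out = []
    for row in test_z:
        dists = [
            (float(np.sqrt(((row - t) ** 2).sum())), idx)
            for idx, t in enumerate(train_z)
        ]
        dists.sort(key=lambda pair: (pair[0], pair[1]))
        nearest = dists[:k]
        votes: dict = {}
        for _, idx in nearest:
            votes[train_labels[idx]] = votes.get(train_labels[idx], 0) + 1
        best = max(votes.values())
        tied = {lab for lab, v in votes.items() if v == best}
        for _, idx in nearest:
            if train_labels[idx] in tied:
                out.append(train_labels[idx])
                break
    return out


def roc_auc_bruteforce(y_true, scores):
    """Exhaustive threshold-sweep ROC points and trapezoidal AUC.

    Thresholds are every distinct score (prediction: score >= threshold),
    plus one above the maximum for the (0, 0) corner.
    """
    y = [bool(v) for v in y_true]
    s = [float(v) for v in scores]
    pos = sum(y)
    neg = len(y) - pos
    thresholds = sorted(set(s), reverse=True)
    points = [(0.0, 0.0)]
    for thr in thresholds:
        tp = sum(1 for yi, si in zip(y, s) if yi and si >= thr)
        fp = sum(1 for yi, si in zip(y, s) if not yi and si >= thr)
        points.append((fp / neg, tp / pos))
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return points, auc


def one_way_ss(groups):
    """Hand sums-of-squares for a one-way layout (list of lists)."""
    allv = [v for g in groups for v in g]
    gm = sum(allv) / len(allv)
    ssb = sum(len(g) * (sum(g) / len(g) - gm) ** 2 for g in groups)
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    f = (ssb / df_b) / (ssw / df_w)
    return ssb, ssw, df_b, df_w, f


def ols_normal_equations(x, y):
    """Direct solve of (X'X) b = X'y with a prepended intercept column."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    design = np.hstack([np.ones((len(x), 1)), x])
    xtx = design.T @ design
    xty = design.T @ y
    return np.linalg.solve(xtx, xty)
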