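"""Independent brute-force oracles used by the tests.

Everything here is written as plain nested loops straight from the
defining formulas, deliberately sharing no code with the package, so
agreement is evidence of correctness rather than of shared bugs.
"""

from __future__ import annotations

import math

import numpy as np


def _cheb(a, b) -> float:
    return max(abs(p - q) for p, q in zip(a, b))


def ae_brute(x, m: int = 2, r_factor: float = 0.2) -> float:
    """Approximate entropy by direct template counting (self-matches in)."""
    x = list(map(float, x))
    n = len(x)
    r = r_factor * float(np.std(x))

    def phi(mm):
        temps = [x[i : i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for ti in temps:
            c = sum(1 for tj in temps if _cheb(ti, tj) <= r)
            total += math.log(c / len(temps))
        return total / len(temps)

    return phi(m) - phi(m + 1)


def se_brute(x, m: int = 2, r_factor: float = 0.2) -> float:
    """Sample entropy by exhaustive pair enumeration (self-matches out)."""
    x = list(map(float, x))
    n = len(x)
    r = r_factor * float(np.std(x))
    nt = n - m
    tm = [x[i : i + m] for i in range(nt)]
    tm1 = [x[i : i + m + 1] for i in range(nt)]
    b = sum(
        1 for i in range(nt) for j in range(nt) if i != j and _cheb(tm[i], tm[j]) <= r
    )
    a = sum(
        1 for i in range(nt) for j in range(nt) if i != j and _cheb(tm1[i], tm1[j]) <= r
    )
    if b == 0:
        return 0.0
    if a == 0:
        return math.log(b)
    return -math.log(a / b)


def fe_brute(x, m: int = 2, r_factor: float = 0.2, n_grad: int = 2) -> float:
    """Fuzzy entropy by summing membership grades over all template pairs."""
    x = list(map(float, x))
    n = len(x)
    r = r_factor * float(np.std(x))

    def phi(mm):
        temps = []
        for i in range(n - m):
            t = x[i : i + mm]
            mu = sum(t) / mm
            temps.append([v - mu for v in t])
        total = 0.0
        for i in range(len(temps)):
            for j in range(len(temps)):
                if i != j:
                    total += math.exp(-((_cheb(temps[i], temps[j]) / r) ** n_grad))
        return total / (len(temps) * (len(temps) - 1))

    return math.log(phi(m)) - math.log(phi(m + 1))


def roc_auc_threshold_enum(scores, labels, positive) -> float:
    """ROC area by exhaustive threshold enumeration + trapezoid rule."""
    scores = list(map(float, scores))
    y = [1 if l == positive else 0 for l in labels]
    npos, nneg = sum(y), len(y) - sum(y)
    thresholds = sorted(set(scores), reverse=True)
    pts = [(0.0, 0.0)]
    for th in thresholds:
        tp = sum(1 for s, yy in zip(scores, y) if s >= th and yy == 1)
        fp = sum(1 for s, yy in zip(scores, y) if s >= th and yy == 0)
        pts.append((fp / nneg, tp / npos))
    pts.append((1.0, 1.0))
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


def roc_auc_rank_stat(scores, labels, positive) -> float:
    """ROC area as the Mann-Whitney pairwise-comparison statistic."""
    pos = [float(s) for s, l in zip(scores, labels) if l == positive]
    neg = [float(s) for s, l in zip(scores, labels) if l != positive]
    wins = sum(
        1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
    )
    return wins / (len(pos) * len(neg))


def eq2_weights_brute(single, pairwise) -> list[float]:
    """Electrode weights by direct summation of the defining formula."""
    n = len(single)
    out = []
    for i in range(n):
        dev = 0.0
        for j in range(n):
            if j != i:
                dev += pairwise[i][j] + single[i] - single[j]
        out.append(single[i] + dev / n)
    return out
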