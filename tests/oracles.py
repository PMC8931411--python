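"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the implementations under test: DTW by
exhaustive enumeration of monotone warping paths, the silhouette by a
literal loop transcription of its defining formulas, and the Gaussian
fit by grid search plus derivative-free refinement.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def brute_force_dtw(a, b) -> float:
    """Minimum cumulative |a_i - b_j| over all monotone warping paths.

    Enumerates every path from (0, 0) to (m-1, n-1) using steps
    (+1, 0), (0, +1), (+1, +1).  Exponential: keep len <= 8.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m, n = len(a), len(b)
    best = [np.inf]

    def walk(i: int, j: int, cost: float) -> None:
        cost += abs(a[i] - b[j])
        if i == m - 1 and j == n - 1:
            if cost < best[0]:
                best[0] = cost
            return
        if i + 1 < m:
            walk(i + 1, j, cost)
        if j + 1 < n:
            walk(i, j + 1, cost)
        if i + 1 < m and j + 1 < n:
            walk(i + 1, j + 1, cost)

    walk(0, 0, 0.0)
    return best[0]


def brute_force_silhouette(X, labels) -> tuple[np.ndarray, float]:
    """Literal per-point transcription of the silhouette definition."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(X)
    s = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            s[i] = 0.0
            continue
        a_i = sum(np.linalg.norm(X[i] - X[j]) for j in same) / len(same)
        b_candidates = []
        for lab in set(labels.tolist()) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == lab]
            b_candidates.append(sum(np.linalg.norm(X[i] - X[j]) for j in other) / len(other))
        b_i = min(b_candidates)
        denom = max(a_i, b_i)
        s[i] = (b_i - a_i) / denom if denom > 0 else 0.0
    return s, float(np.mean(s))


def grid_search_gaussian(t, y) -> np.ndarray:
    """Fit a*exp(-((t-b)/c)^2) by coarse grid search + Nelder-Mead."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)

    def sse(p):
        a, b, c = p
        return float(np.sum((y - a * np.exp(-(((t - b) / c) ** 2))) ** 2))

    amps = np.linspace(-1.5, 1.5, 31)
    centers = np.linspace(t.min() - 20, t.max() + 20, 31)
    widths = np.linspace(5, (t.max() - t.min()), 20)
    best, best_val = None, np.inf
    for a in amps:
        if a == 0:
            continue
        for b in centers:
            for c in widths:
                v = sse((a, b, c))
                if v < best_val:
                    best, best_val = (a, b, c), v
    res = minimize(sse, best, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 20000})
    out = np.asarray(res.x, dtype=float)
    out[2] = abs(out[2])
    return out
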