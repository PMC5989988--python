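"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: plain loops,
exhaustive enumeration and a pool-adjacent-violators fit via
sklearn.isotonic, so that agreement is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def strength_oracle(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            out[i] += W[i, j]
    return out


def density_oracle(W: np.ndarray) -> float:
    n = W.shape[0]
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > 0:
                count += 1
    return count / (n * (n - 1) / 2)


def clustering_oracle(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    wmax = W.max()
    if wmax == 0:
        return np.zeros(n)
    Wh = W / wmax
    out = np.zeros(n)
    for i in range(n):
        if sum(1 for j in range(n) if W[i, j] > 0) < 2:
            continue
        num = 0.0
        for j in range(n):
            for k in range(n):
                if j != k and j != i and k != i:
                    num += Wh[i, j] * Wh[j, k] * Wh[k, i]
        s = sum(Wh[i, j] for j in range(n))
        den = s * s - sum(Wh[i, j] ** 2 for j in range(n))
        out[i] = num / den if den > 0 else 0.0
    return out


def path_strength_oracle(W: np.ndarray, i: int, j: int) -> float:
    """Exhaustive simple-path enumeration; NaN when no path exists."""
    n = W.shape[0]
    others = [k for k in range(n) if k not in (i, j)]
    best = math.inf
    for r in range(len(others) + 1):
        for mid in itertools.permutations(others, r):
            path = (i, *mid, j)
            total = 0.0
            ok = True
            for a, b in zip(path[:-1], path[1:]):
                if W[a, b] <= 0:
                    ok = False
                    break
                total += 1.0 / W[a, b]
            if ok:
                best = min(best, total)
    return 1.0 / best if math.isfinite(best) else float("nan")


def mean_path_length_oracle(W: np.ndarray) -> float:
    n = W.shape[0]
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            L = path_strength_oracle(W, i, j)
            if not math.isnan(L):
                vals.append(L)
    return float(np.mean(vals)) if vals else float("nan")


def mann_whitney_exact_oracle(a, b) -> tuple[float, float]:
    """Full enumeration of group assignments (tie-free samples only)."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    na = len(a)
    m = na * len(b)

    def u_stat(first):
        rest = [v for v in pooled if v not in first]
        return sum(1 for x in first for y in rest if x > y)

    u_obs = sum(1 for x in a for y in b if x > y)
    lo = min(u_obs, m - u_obs)
    total = hits = 0
    for combo in itertools.combinations(pooled, na):
        u = u_stat(set(combo))
        total += 1
        if u <= lo or u >= m - lo:
            hits += 1
    return float(u_obs), min(1.0, hits / total)


def grenander_pava_oracle(pvalues) -> tuple[np.ndarray, np.ndarray]:
    """LCM slopes via weighted antitonic regression of the empirical
    density (pool-adjacent-violators through sklearn.isotonic).

    Returns (interval right endpoints, fitted slopes); assumes all p > 0.
    """
    from sklearn.isotonic import IsotonicRegression

    p = np.sort(np.asarray(pvalues, dtype=float))
    n = p.size
    x, counts = np.unique(p, return_counts=True)
    y = np.cumsum(counts) / n
    xs = np.concatenate([[0.0], x])
    ys = np.concatenate([[0.0], y])
    if xs[-1] < 1.0:
        xs = np.append(xs, 1.0)
        ys = np.append(ys, 1.0)
    dx = np.diff(xs)
    emp = np.diff(ys) / dx
    iso = IsotonicRegression(increasing=False)
    fitted = iso.fit_transform(np.arange(len(emp)), emp, sample_weight=dx)
    return xs[1:], fitted


def partial_spearman_residual_oracle(x, y, z) -> float:
    """Regress ranks of x and y on covariate ranks, correlate residuals."""
    from scipy.stats import rankdata

    rx, ry, rz = rankdata(x), rankdata(y), rankdata(z)
    X = np.column_stack([np.ones_like(rz), rz])
    res_x = rx - X @ np.linalg.lstsq(X, rx, rcond=None)[0]
    res_y = ry - X @ np.linalg.lstsq(X, ry, rcond=None)[0]
    return float(np.corrcoef(res_x, res_y)[0, 1])
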