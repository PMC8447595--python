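"""Independent brute-force reference implementations used only by tests.

Each oracle is written from the mathematical definition with plain loops,
deliberately sharing no code path with the package, so agreement is
evidence of correctness rather than self-consistency.
"""

from __future__ import annotations

import numpy as np


def brute_quantile(values, q):
    """Linear-interpolation quantile from the order statistics, by hand."""
    v = sorted(float(x) for x in values)
    n = len(v)
    if n == 1:
        return v[0]
    pos = q * (n - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def brute_fences(values):
    """(q1, q3, n_outliers) with 1.5*IQR fences by direct enumeration."""
    q1 = brute_quantile(values, 0.25)
    q3 = brute_quantile(values, 0.75)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    n_out = sum(1 for x in values if x < lo or x > hi)
    return q1, q3, n_out


def brute_local_regression(x, y, span, degree):
    """Point-by-point local polynomial regression with tricube weights.

    Window = ceil(span*n) nearest neighbours of the target; weighted normal
    equations solved explicitly per point.
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    k = min(n, max(int(np.ceil(span * n)), degree + 1))
    fitted = []
    for i in range(n):
        dists = sorted(range(n), key=lambda j: (abs(x[j] - x[i]), j))
        window = dists[:k]
        dmax = max(abs(x[j] - x[i]) for j in window)
        if dmax == 0:
            fitted.append(sum(y[j] for j in window) / len(window))
            continue
        ws, rows, ys = [], [], []
        for j in window:
            u = abs(x[j] - x[i]) / dmax
            w = (1 - u**3) ** 3
            ws.append(w)
            rows.append([(x[j] - x[i]) ** p for p in range(degree + 1)])
            ys.append(y[j])
        W = np.diag(ws)
        A = np.array(rows)
        b = np.array(ys)
        # normal equations A' W A beta = A' W b
        beta = np.linalg.solve(A.T @ W @ A, A.T @ W @ b)
        fitted.append(beta[0])
    return np.array(fitted)


def brute_quantile_normalize(columns: dict) -> dict:
    """Quantile normalization via interpolated per-sample quantile functions.

    columns: sample -> list of (row_key, value) observed entries.
    Returns sample -> list of (row_key, normalized value).
    """
    m = max(len(v) for v in columns.values())
    grid = [j / (m - 1) for j in range(m)]
    ref = [0.0] * m
    for entries in columns.values():
        vals = [v for _, v in entries]
        for j, p in enumerate(grid):
            ref[j] += brute_quantile(vals, p)
    ref = [r / len(columns) for r in ref]

    out = {}
    for sample, entries in columns.items():
        vals = [v for _, v in entries]
        n_s = len(vals)
        # average fractional ranks with ties
        sorted_vals = sorted(vals)
        res = []
        for key, v in entries:
            positions = [i for i, sv in enumerate(sorted_vals) if sv == v]
            rank = sum(positions) / len(positions)  # 0-based average rank
            frac = rank / (n_s - 1)
            res.append((key, float(np.interp(frac, grid, ref))))
        out[sample] = res
    return out


def brute_average_linkage(D: np.ndarray):
    """O(n^3) average-linkage agglomeration on a square distance matrix.

    Returns the sorted list of merge heights (comparable to scipy linkage
    heights regardless of cluster labelling).
    """
    n = D.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return sorted(heights)


def brute_combat(Y: np.ndarray, batch_idx: np.ndarray, conv: float = 1.0e-4,
                 max_iter: int = 100) -> np.ndarray:
    """Line-by-line parametric EB location-scale adjustment, complete data.

    Y: features x samples (no missing values); batch_idx: integer batch of
    each sample.  Follows the standard parametric algorithm: feature-wise
    standardization against the batch-size-weighted grand mean and pooled
    variance, moment-matched normal prior on locations and inverse-gamma
    prior on variances, iterated conditional posterior means, and
    back-transformation.
    """
    G, S = Y.shape
    batches = sorted(set(int(b) for b in batch_idx))
    nb = {b: int((batch_idx == b).sum()) for b in batches}

    gamma_hat = np.zeros((G, len(batches)))
    delta_hat = np.zeros((G, len(batches)))
    grand = np.zeros(G)
    varp = np.zeros(G)
    Z = np.zeros_like(Y, dtype=float)
    for g in range(G):
        batch_means = {b: Y[g, batch_idx == b].mean() for b in batches}
        grand[g] = sum(nb[b] * batch_means[b] for b in batches) / S
        resid_sq = 0.0
        for s in range(S):
            resid_sq += (Y[g, s] - batch_means[int(batch_idx[s])]) ** 2
        varp[g] = resid_sq / S
        for s in range(S):
            Z[g, s] = (Y[g, s] - grand[g]) / np.sqrt(varp[g])
        for j, b in enumerate(batches):
            zb = Z[g, batch_idx == b]
            gamma_hat[g, j] = zb.mean()
            delta_hat[g, j] = zb.var(ddof=1)

    out = np.zeros_like(Y, dtype=float)
    for j, b in enumerate(batches):
        gh = gamma_hat[:, j]
        dh = delta_hat[:, j]
        gbar = gh.mean()
        t2 = gh.var(ddof=1)
        m = dh.mean()
        s2 = dh.var(ddof=1)
        a_pr = (2 * s2 + m**2) / s2
        b_pr = (m * s2 + m**3) / s2
        n = nb[b]
        Zb = Z[:, batch_idx == b]
        g_old, d_old = gh.copy(), dh.copy()
        for _ in range(max_iter):
            g_new = (n * t2 * gh + d_old * gbar) / (n * t2 + d_old)
            sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b_pr) / (n / 2.0 + a_pr - 1.0)
            change = max(
                np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
                np.abs(d_new - d_old).max() / max(np.abs(d_old).max(), 1e-12),
            )
            g_old, d_old = g_new, d_new
            if change <= conv:
                break
        cols = np.flatnonzero(batch_idx == b)
        for g in range(G):
            for s in cols:
                out[g, s] = (
                    (Z[g, s] - g_old[g]) / np.sqrt(d_old[g]) * np.sqrt(varp[g]) + grand[g]
                )
    return out


def brute_cramers_v(table: np.ndarray) -> float:
    """Cramér's V from the chi-square statistic, computed by loops."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            exp = rows[i] * cols[j] / n
            if exp > 0:
                chi2 += (table[i, j] - exp) ** 2 / exp
    k = min(table.shape) - 1
    return float(np.sqrt(chi2 / (n * k))) if k > 0 else 0.0
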