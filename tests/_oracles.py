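"""Independent brute-force reference implementations used only by tests.

Deliberately naive (triple loops, Floyd–Warshall, direct formula evaluation)
so they share no code path with the package.
"""

import numpy as np


def pearson_direct(x, y):
    """Correlation from the definitional covariance / sigma formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cx = x - x.mean()
    cy = y - y.mean()
    cov = (cx * cy).mean()
    return cov / (np.sqrt((cx**2).mean()) * np.sqrt((cy**2).mean()))


def bf_degree(w):
    n = len(w)
    d = np.array([sum(1 for j in range(n) if w[i][j] != 0) for i in range(n)], float)
    return d, d.mean() if n else 0.0


def bf_strength(w):
    n = len(w)
    s = np.array([sum(w[i][j] for j in range(n)) / n for i in range(n)])
    return s, s.mean() if n else 0.0


def bf_path_matrix(w):
    """Floyd–Warshall on edge lengths 1/w; inf marks unreachable."""
    n = len(w)
    dist = np.full((n, n), np.inf)
    for i in range(n):
        dist[i, i] = 0.0
        for j in range(n):
            if i != j and w[i][j] > 0:
                dist[i, j] = 1.0 / w[i][j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def bf_path_length_average(w):
    """LA with the zero-for-unreachable convention and N(N-1) normalizer."""
    n = len(w)
    if n < 2:
        return 0.0
    dist = bf_path_matrix(w)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]):
                total += dist[i, j]
    return total / (n * (n - 1))


def bf_clustering(w, normalize=True):
    """Geometric-mean triangle clustering by exhaustive enumeration."""
    w = np.asarray(w, float)
    n = len(w)
    if normalize and w.max() > 0:
        wn = w / w.max()
    else:
        wn = w
    c = np.zeros(n)
    for i in range(n):
        d = sum(1 for j in range(n) if w[i][j] != 0)
        if d < 2:
            continue
        total = 0.0
        for j in range(n):
            for k in range(n):
                if j != k and j != i and k != i:
                    total += (wn[i][j] * wn[j][k] * wn[k][i]) ** (1.0 / 3.0)
        c[i] = total / (d * (d - 1))
    return c, c.mean() if n else 0.0


def random_weighted_graph(rng, n, density=0.5):
    """Random symmetric non-negative weight matrix with zero diagonal."""
    w = rng.uniform(0.05, 1.0, size=(n, n))
    mask = rng.random((n, n)) < density
    w = np.triu(w * mask, 1)
    return w + w.T
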