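"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's code paths (and scipy's ranking),
so they can serve as independent references for the statistics they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_ranks(row) -> list:
    """Average ranks of one sequence, computed from first principles."""
    row = list(row)
    order = sorted(range(len(row)), key=lambda i: row[i])
    ranks = [0.0] * len(row)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and row[order[j + 1]] == row[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0  # mean of 1-based positions i..j
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_force_kendalls_w(series) -> float:
    """Tie-corrected Kendall's W by direct summation (pure-python ranks)."""
    series = np.asarray(series, dtype=float)
    k, n = series.shape
    ranks = np.array([brute_force_ranks(r) for r in series])
    col_sums = ranks.sum(axis=0)
    mean_r = k * (n + 1) / 2.0
    s = float(((col_sums - mean_r) ** 2).sum())
    tie = 0.0
    for row in series:
        _, counts = np.unique(row, return_counts=True)
        tie += float((counts.astype(float) ** 3 - counts).sum())
    denom = k * k * (n**3 - n) - k * tie
    if denom <= 0:
        return float("nan")
    return 12.0 * s / denom


def heat_diffusion_step(x, adjacency, areas, tau) -> np.ndarray:
    """Explicit diffusion step written as a per-vertex loop (oracle)."""
    adjacency = adjacency.tocsr()
    out = np.array(x, dtype=float)
    for v in range(len(x)):
        nbrs = adjacency.indices[adjacency.indptr[v]: adjacency.indptr[v + 1]]
        flux = sum(0.5 * (areas[v] + areas[u]) * (x[u] - x[v]) for u in nbrs)
        out[v] = x[v] + tau / areas[v] * flux
    return out


def ols_residuals(y, X) -> np.ndarray:
    """Normal-equations least squares residuals (oracle)."""
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return y - X @ beta


def dice(a, b) -> float:
    a, b = set(map(int, a)), set(map(int, b))
    if not a and not b:
        return 1.0
    return 2.0 * len(a & b) / (len(a) + len(b))
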