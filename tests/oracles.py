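"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, textbook recursions)
and shares no code with the package paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def nw_score(a: str, b: str, matrix, gap: int = 10) -> int:
    """Textbook Needleman-Wunsch global score with linear gap cost.

    ``matrix`` is a pandas DataFrame indexed by residue letters.
    """
    n, m = len(a), len(b)
    F = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        F[i][0] = -gap * i
    for j in range(1, m + 1):
        F[0][j] = -gap * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            F[i][j] = max(
                F[i - 1][j - 1] + int(matrix.loc[a[i - 1], b[j - 1]]),
                F[i - 1][j] - gap,
                F[i][j - 1] - gap,
            )
    return F[n][m]


def brute_force_ln_diversity(freqs, dist, q: float, lam: float) -> float:
    """Direct evaluation of D(q, lambda) from its defining sums.

    ``lam=math.inf`` means the identity kernel (naive diversity).  No
    log-space tricks: plain powers and sums, so only valid where they do not
    underflow — which is the case for the small test fixtures it is used on.
    """
    p = np.asarray(freqs, dtype=float)
    S = p.size
    if math.isinf(lam):
        zp = p.copy()
    else:
        zp = np.zeros(S)
        for i in range(S):
            acc = 0.0
            for j in range(S):
                acc += math.exp(-lam * dist[i][j]) * p[j]
            zp[i] = acc
    if math.isinf(q):
        return -math.log(max(zp))
    if q == 1.0:
        return -float(sum(p[i] * math.log(zp[i]) for i in range(S)))
    total = float(sum(p[i] * zp[i] ** (q - 1.0) for i in range(S)))
    return math.log(total) / (1.0 - q)


def brute_force_grid(freqs, dist, q_values, lambda_values) -> np.ndarray:
    """ln D over a full (q, lambda) grid via the naive sums."""
    out = np.empty((len(q_values), len(lambda_values)))
    for i, q in enumerate(q_values):
        for j, lam in enumerate(lambda_values):
            out[i, j] = brute_force_ln_diversity(freqs, dist, q, lam)
    return out


def complete_linkage_heights(X) -> list[float]:
    """Merge heights of naive O(n^3) complete-linkage agglomeration."""
    X = np.asarray(X, dtype=float)
    clusters: list[list[int]] = [[i] for i in range(len(X))]
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    heights = []
    while len(clusters) > 1:
        best = (math.inf, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                h = max(d[i, j] for i in clusters[a] for j in clusters[b])
                if h < best[0]:
                    best = (h, (a, b))
        h, (a, b) = best
        heights.append(h)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


def pca_eigen_scores(X) -> tuple[np.ndarray, np.ndarray]:
    """(scores, explained fractions) from an explicit covariance eigendecomposition."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (len(X) - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    w = np.maximum(w, 0.0)
    return Xc @ v, w / w.sum()
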