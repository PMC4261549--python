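"""Brute-force oracle implementations shared by acceptance tests.

These are deliberately naive O(n^2)/loop-based computations, independent
of the package's vectorized code paths.
"""

import numpy as np

from vitabind.selection import LAPLACIAN_WORST


def brute_variance(X):
    M, D = X.shape
    out = np.empty(D)
    for j in range(D):
        m = sum(X[:, j]) / M
        out[j] = sum((x - m) ** 2 for x in X[:, j]) / (M - 1)
    return out


def brute_fisher(X, y):
    M, D = X.shape
    out = np.empty(D)
    for j in range(D):
        mu = sum(X[:, j]) / M
        num = den = 0.0
        for c in (0, 1):
            block = [x for x, t in zip(X[:, j], y) if t == c]
            n_c = len(block)
            mu_c = sum(block) / n_c
            var_c = sum((x - mu_c) ** 2 for x in block) / n_c
            num += n_c * (mu_c - mu) ** 2
            den += n_c * var_c
        if den > 0:
            out[j] = num / den
        elif num > 0:
            out[j] = num / np.finfo(float).eps
        else:
            out[j] = 0.0
    return out


def brute_laplacian(X, knn):
    M, D = X.shape
    d2 = np.zeros((M, M))
    for i in range(M):
        for k in range(M):
            d2[i, k] = sum((X[i] - X[k]) ** 2)
    heat_t = d2[np.triu_indices(M, k=1)].mean()
    S = np.zeros((M, M))
    for i in range(M):
        order = [j for j in np.argsort(d2[i], kind="stable") if j != i][:knn]
        for j in order:
            S[i, j] = np.exp(-d2[i, j] / heat_t)
    S = np.maximum(S, S.T)
    deg = S.sum(axis=1)
    Dm = np.diag(deg)
    L = Dm - S
    one = np.ones(M)
    out = np.empty(D)
    for j in range(D):
        f = X[:, j]
        ft = f - (f @ Dm @ one) / (one @ Dm @ one)
        den = ft @ Dm @ ft
        out[j] = LAPLACIAN_WORST if den <= 1e-300 else min(
            (ft @ L @ ft) / den, LAPLACIAN_WORST
        )
    return out


def brute_auc(scores, y):
    pairs = wins = 0.0
    for si, ti in zip(scores, y):
        for sj, tj in zip(scores, y):
            if ti == 1 and tj == 0:
                pairs += 1
                wins += 1.0 if si > sj else 0.5 if si == sj else 0.0
    return wins / pairs
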