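"""Feature scoring and subspace selection.

Four selectors are provided: per-column data variance, the two-class
Fisher score, the Laplacian score (He et al.'s locality-preserving
criterion), and a joint Laplacian feature-weights learner that sizes its
subspace automatically through a sparsity parameter epsilon.

Orientation differs between methods: variance and Fisher rank high
scores best, the Laplacian score ranks low scores best.  The
``higher_is_better`` flag on :class:`FeatureWeights` records this so
:func:`select_top_k` can be used uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .features import FeatureMatrix

#: Upper bound of the Rayleigh quotient f'Lf / f'Df for L = D - S with
#: nonnegative S; used as the worst-rank sentinel for degenerate columns.
LAPLACIAN_WORST = 2.0

#: Weights at or below this value count as zero for automatic sizing.
WEIGHT_ZERO_TOL = 1e-12


@dataclass
class FeatureWeights:
    """Per-feature importance scores from one selection method."""

    weights: np.ndarray
    method: str
    higher_is_better: bool = True
    converged: bool = True
    objective_history: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isfinite(self.weights).all():
            raise ValueError("feature weights must be finite")


@dataclass
class FeatureSubspace:
    """An ordered set of selected feature-column indices."""

    indices: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("subspace indices must be unique")
        if (np.diff(self.indices) <= 0).any():
            raise ValueError("subspace indices must be sorted ascending")

    @property
    def k(self) -> int:
        return len(self.indices)


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _labels_of(X, y=None) -> np.ndarray:
    if y is not None:
        return np.asarray(y)
    if isinstance(X, FeatureMatrix) and X.labels is not None:
        return np.asarray(X.labels)
    raise ValueError("labels required but not supplied")


def variance_score(X) -> FeatureWeights:
    """Per-column sample variance (denominator M-1)."""
    data = _as_array(X)
    if data.shape[0] < 2:
        raise ValueError("variance requires at least 2 samples")
    return FeatureWeights(weights=data.var(axis=0, ddof=1), method="variance")


def fisher_score(X, y=None) -> FeatureWeights:
    """Two-class Fisher score per column.

    score_j = sum_c n_c (mu_cj - mu_j)^2 / sum_c n_c sigma_cj^2 with
    per-class biased variances.  A column with zero pooled within-class
    variance but nonzero class separation is a perfect separator and
    receives the between-class numerator over a machine-epsilon floor so
    that it outranks every finitely scored column.
    """
    data = _as_array(X)
    labels = _labels_of(X, y)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"fisher score requires exactly 2 classes, got {len(classes)}")
    mu = data.mean(axis=0)
    num = np.zeros(data.shape[1])
    den = np.zeros(data.shape[1])
    for c in classes:
        block = data[labels == c]
        n_c = block.shape[0]
        num += n_c * (block.mean(axis=0) - mu) ** 2
        den += n_c * block.var(axis=0)  # biased per-class variance
    eps_floor = np.finfo(float).eps
    scores = np.where(
        den > 0, num / np.maximum(den, eps_floor), np.where(num > 0, num / eps_floor, 0.0)
    )
    return FeatureWeights(weights=scores, method="fisher")


def _knn_heat_graph(
    data: np.ndarray, knn: int, heat_t: Optional[float] = None
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetric kNN similarity graph with heat-kernel weights.

    Neighbours are chosen by squared Euclidean distance with ties broken
    deterministically by index (stable argsort).  ``heat_t`` defaults to
    the mean squared pairwise distance.  Returns (S, D, L) as dense
    arrays with D the degree matrix and L = D - S.
    """
    M = data.shape[0]
    if not (1 <= knn < M):
        raise ValueError(f"need 1 <= knn < n_samples, got knn={knn}, M={M}")
    d2 = squareform(pdist(data, metric="sqeuclidean"))
    if heat_t is None:
        off = d2[np.triu_indices(M, k=1)]
        heat_t = float(off.mean()) if off.size else 1.0
    if heat_t <= 0:
        heat_t = 1.0
    sim = np.exp(-d2 / heat_t)
    order = np.argsort(d2, axis=1, kind="stable")
    S = np.zeros((M, M))
    for i in range(M):
        neigh = [j for j in order[i] if j != i][:knn]
        S[i, neigh] = sim[i, neigh]
    S = np.maximum(S, S.T)
    deg = S.sum(axis=1)
    D = np.diag(deg)
    L = D - S
    return S, D, L


def _locality_ratios(data: np.ndarray, deg: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Per-column ratio f~'Lf~ / f~'Df~ with f~ mean-centred under D."""
    total = deg.sum()
    ratios = np.empty(data.shape[1])
    for j in range(data.shape[1]):
        f = data[:, j]
        f_t = f - (f @ deg) / total
        den = f_t @ (deg * f_t)
        if den <= 1e-300:
            ratios[j] = LAPLACIAN_WORST
        else:
            ratios[j] = float(f_t @ (L @ f_t)) / den
    return np.clip(ratios, 0.0, LAPLACIAN_WORST)


def laplacian_score(X, knn: int = 5, heat_t: Optional[float] = None) -> FeatureWeights:
    """Laplacian score per column; lower scores are more locality-preserving.

    Constant columns (zero D-weighted variance) receive the worst-rank
    sentinel ``LAPLACIAN_WORST``.
    """
    data = _as_array(X)
    _, D, L = _knn_heat_graph(data, knn=knn, heat_t=heat_t)
    ratios = _locality_ratios(data, np.diag(D), L)
    return FeatureWeights(weights=ratios, method="laplacian", higher_is_better=False)


def jlfwl(
    X,
    epsilon: float = 0.5,
    max_iter: int = 30,
    tol: float = 1e-6,
    knn: int = 5,
    heat_t: Optional[float] = None,
    seed: Optional[int] = None,
) -> Tuple[FeatureWeights, FeatureSubspace]:
    """Joint Laplacian feature-weights learning with automatic sizing.

    The weights are learned jointly: each iteration (i) builds a kNN
    heat-kernel graph on the *weight-scaled* data, so every feature's
    weight influences every other feature's locality ratio; (ii) computes
    per-feature Laplacian locality ratios r_j on that graph; (iii)
    soft-thresholds them, w_j = max(0, theta - r_j), with the cut placed
    relative to the ratio distribution, theta = mean(r) + std(r)/epsilon
    (capped just below the worst ratio so any positive epsilon excludes
    at least that feature), then rescales to max weight 1.  Larger
    epsilon lowers theta and drives more weights to exact zero, trimming
    the tail of worst (least locality-preserving) features first; at the
    epsilon = 0.5 default the cut sits two standard deviations above the
    mean, so only a small tail of clearly uninformative features is
    dropped, and epsilon = 0 keeps every feature.  The objective — the weighted mean
    locality ratio sum_j w_j r_j / sum_j w_j — is monotone by
    construction: an update is only accepted while it decreases,
    otherwise the best iterate so far is returned with ``converged`` set
    accordingly.

    The subspace is the set of features with weight above
    ``WEIGHT_ZERO_TOL``; its size is an output, never an input.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    data = _as_array(X)
    if data.size == 0:
        raise ValueError("empty feature matrix")
    D = data.shape[1]

    w = np.ones(D)
    best_w = w
    best_J = np.inf
    history: List[float] = []
    converged = False

    for _ in range(max_iter):
        _, Dg, L = _knn_heat_graph(data * w, knn=knn, heat_t=heat_t)
        r = _locality_ratios(data, np.diag(Dg), L)
        J = float((w * r).sum() / w.sum())
        if J > best_J - tol:
            converged = True
            break
        history.append(J)
        best_J, best_w = J, w

        r_std = float(r.std())
        if r_std < 1e-15 or epsilon == 0:
            w = np.ones(D)  # symmetric input or no sparsity pressure
            continue
        theta = float(r.mean()) + r_std / epsilon
        # any positive epsilon exerts sparsity pressure: at minimum the
        # single worst-ratio feature is excluded
        r_max = float(r.max())
        theta = min(theta, r_max - 1e-12 * max(1.0, abs(r_max)))
        w_new = np.maximum(theta - r, 0.0)
        w_new /= w_new.max()
        w = w_new

    weights = FeatureWeights(
        weights=best_w,
        method="jlfwl",
        higher_is_better=True,
        converged=converged,
        objective_history=history,
    )
    idx = np.flatnonzero(best_w > WEIGHT_ZERO_TOL)
    return weights, FeatureSubspace(indices=idx, method="jlfwl")


def select_top_k(weights: FeatureWeights, k: int) -> FeatureSubspace:
    """Select the k best columns per the method's orientation.

    Ties at the cut are broken in favour of the lower column index.
    """
    D = len(weights.weights)
    if not (1 <= k <= D):
        raise ValueError(f"k must be in [1,{D}], got {k}")
    key = -weights.weights if weights.higher_is_better else weights.weights
    chosen = np.argsort(key, kind="stable")[:k]
    return FeatureSubspace(indices=np.sort(chosen), method=weights.method)
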