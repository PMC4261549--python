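"""Heterogeneous subspace SVM ensemble.

One RBF C-SVM is trained per selected feature subspace; at prediction
time the per-member probability scores are combined by an unweighted
arithmetic mean and thresholded (strictly greater than T) to call
binding residues.  Platt-style probability estimates put every member's
output on a common [0,1] scale before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import joblib
import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureMatrix, PropensityTable
from .selection import (
    FeatureSubspace,
    fisher_score,
    jlfwl,
    laplacian_score,
    select_top_k,
    variance_score,
)

ARCHIVE_VERSION = "vitabind-model-1"

# LIBSVM's published exponential grids, coarsened to a step of 2^4 for
# desk-scale work.  sigma is parameterized as gamma = 1/(2 sigma^2), so
# a larger kernel width means a smaller gamma.
DEFAULT_C_GRID: Tuple[float, ...] = tuple(2.0 ** e for e in range(-5, 16, 4))
DEFAULT_GAMMA_GRID: Tuple[float, ...] = tuple(2.0 ** e for e in range(-15, 4, 4))

DEFAULT_SELECTORS = ("jlfwl", "fisher", "laplacian")


def grid_search_svm(
    X_sub: np.ndarray,
    y: np.ndarray,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    inner_folds: int = 3,
    seed: int = 0,
) -> Tuple[float, float]:
    """Pick (C, gamma) maximizing inner-CV AUC.

    Ties are broken toward the smaller C, then the larger kernel width
    (smaller gamma) — the smoother model.  A 1x1 grid short-circuits
    without cross-validation.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("grid search requires both classes present")
    if not C_grid or not gamma_grid:
        raise ValueError("hyperparameter grids must be non-empty")
    if len(C_grid) == 1 and len(gamma_grid) == 1:
        return float(C_grid[0]), float(gamma_grid[0])

    n_splits = min(inner_folds, int(np.bincount(y).min()))
    if n_splits < 2:
        raise ValueError("too few samples of the minority class for inner CV")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(cv.split(X_sub, y))

    best: Optional[Tuple[float, float]] = None
    best_auc = -np.inf
    # iterate C ascending, gamma ascending: first maximum wins the ties
    for C, gamma in product(sorted(C_grid), sorted(gamma_grid)):
        aucs = []
        for tr, te in folds:
            if len(np.unique(y[te])) < 2:
                continue
            clf = SVC(C=C, gamma=gamma, kernel="rbf")
            clf.fit(X_sub[tr], y[tr])
            aucs.append(roc_auc_score(y[te], clf.decision_function(X_sub[te])))
        mean_auc = float(np.mean(aucs)) if aucs else -np.inf
        if mean_auc > best_auc:
            best_auc, best = mean_auc, (float(C), float(gamma))
    assert best is not None
    return best


@dataclass
class SubspaceModel:
    """One trained ensemble member: a subspace plus its RBF C-SVM."""

    subspace: FeatureSubspace
    svm: SVC
    hyperparams: Tuple[float, float]  # (C, gamma)
    training_meta: Dict[str, int] = field(default_factory=dict)

    def predict_scores(self, X: Union[FeatureMatrix, np.ndarray]) -> np.ndarray:
        data = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
        return self.svm.predict_proba(data[:, self.subspace.indices])[:, 1]


def train_subspace_svm(
    X: Union[FeatureMatrix, np.ndarray],
    y: Optional[np.ndarray],
    subspace: FeatureSubspace,
    hyperparams: Tuple[float, float],
    seed: int = 0,
) -> SubspaceModel:
    """Fit a probability-calibrated RBF C-SVM on the subspace columns."""
    data = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if y is None:
        if not isinstance(X, FeatureMatrix) or X.labels is None:
            raise ValueError("training labels required")
        y = X.labels
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes present")
    C, gamma = hyperparams
    # SVC(probability=True) is LIBSVM's own Platt-scaled -b 1 mode; silence
    # sklearn 1.9's pending deprecation of the flag.
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning, message=".*probability.*")
        svm = SVC(C=C, gamma=gamma, kernel="rbf", probability=True, random_state=seed)
        svm.fit(data[:, subspace.indices], y)
    meta = {"n_pos": int((y == 1).sum()), "n_neg": int((y == 0).sum()), "seed": seed}
    return SubspaceModel(subspace=subspace, svm=svm, hyperparams=(C, gamma), training_meta=meta)


@dataclass
class EnsemblePredictor:
    """A list of subspace SVMs fused by unweighted score averaging."""

    members: List[SubspaceModel]
    threshold: Optional[float] = None
    threshold_strategy: Optional[str] = None
    propensity_table: Optional[PropensityTable] = None
    window: int = 17

    def predict_scores(self, X: Union[FeatureMatrix, np.ndarray]) -> np.ndarray:
        return self.member_scores(X).mean(axis=0)

    def member_scores(self, X: Union[FeatureMatrix, np.ndarray]) -> np.ndarray:
        data = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
        expected = max(m.subspace.indices.max() for m in self.members) + 1
        if data.shape[1] < expected:
            raise ValueError(
                f"feature dimension {data.shape[1]} smaller than training "
                f"dimension (needs >= {expected})"
            )
        return np.vstack([m.predict_scores(data) for m in self.members])

    def classify_scores(self, scores: np.ndarray, threshold: Optional[float] = None) -> np.ndarray:
        T = self.threshold if threshold is None else threshold
        if T is None:
            raise ValueError("no decision threshold set; calibrate or pass one")
        return classify(scores, T)


def classify(scores: np.ndarray, T: float) -> np.ndarray:
    """Binary calls: 1 iff score is strictly above the threshold."""
    return (np.asarray(scores, dtype=float) > T).astype(np.int8)


def _run_selector(name: str, X: FeatureMatrix, y: np.ndarray, *,
                  epsilon: float, knn: int, k: Optional[int],
                  seed: int) -> FeatureSubspace:
    if name == "jlfwl":
        _, sub = jlfwl(X, epsilon=epsilon, knn=knn, seed=seed)
        return sub
    if name == "fisher":
        weights = fisher_score(X, y)
    elif name == "laplacian":
        weights = laplacian_score(X, knn=knn)
    elif name == "variance":
        weights = variance_score(X)
    else:
        raise ValueError(f"unknown selector {name!r}")
    assert k is not None
    return select_top_k(weights, k)


def select_subspaces(
    X: FeatureMatrix,
    y: np.ndarray,
    selectors: Sequence[str],
    *,
    epsilon: float = 0.5,
    knn: int = 5,
    k: Optional[int] = None,
    seed: int = 0,
    graph_sample_cap: int = 1500,
) -> List[FeatureSubspace]:
    """Run the requested selectors on the training matrix.

    The subspace size for the fixed-size selectors (variance / fisher /
    laplacian) defaults to whatever size the joint learner returns on the
    same matrix, mirroring the coupling between the automatic and
    prescribed-size methods; pass ``k`` to override.  Graph-based
    selectors operate on a seeded row subsample when the training matrix
    exceeds ``graph_sample_cap`` rows (dense M x M graphs otherwise grow
    quadratically).
    """
    if not selectors:
        raise ValueError("at least one selector required")
    Xg, yg = X, y
    if X.n_samples > graph_sample_cap:
        rng = np.random.default_rng(seed)
        rows = np.sort(rng.choice(X.n_samples, size=graph_sample_cap, replace=False))
        yg = np.asarray(y)[rows]
        Xg = FeatureMatrix(
            values=X.values[rows],
            block_spans=X.block_spans,
            residue_index=[X.residue_index[i] for i in rows],
            labels=yg,
        )

    jl_sub: Optional[FeatureSubspace] = None
    if k is None:
        if "jlfwl" in selectors:
            _, jl_sub = jlfwl(Xg, epsilon=epsilon, knn=knn, seed=seed)
            k = jl_sub.k
        else:
            _, sizing = jlfwl(Xg, epsilon=epsilon, knn=knn, seed=seed)
            k = sizing.k

    out: List[FeatureSubspace] = []
    for name in selectors:
        if name == "jlfwl" and jl_sub is not None:
            out.append(jl_sub)
        elif name in ("jlfwl", "laplacian"):  # graph-based: capped rows
            out.append(_run_selector(name, Xg, yg, epsilon=epsilon, knn=knn, k=k, seed=seed))
        else:
            out.append(_run_selector(name, X, y, epsilon=epsilon, knn=knn, k=k, seed=seed))
    return out


def train_ensemble(
    X: FeatureMatrix,
    y: Optional[np.ndarray] = None,
    selectors: Sequence[str] = DEFAULT_SELECTORS,
    seed: int = 0,
    *,
    epsilon: float = 0.5,
    knn: int = 5,
    k: Optional[int] = None,
    hyperparams: Optional[Tuple[float, float]] = None,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    inner_folds: int = 3,
    propensity_table: Optional[PropensityTable] = None,
    window: int = 17,
) -> EnsemblePredictor:
    """Train one subspace SVM per selector on a shared training matrix.

    Each member gets its own (C, gamma) from an inner grid search unless
    fixed ``hyperparams`` are supplied.  The decision threshold is left
    unset; calibrate it on scores with an evaluation strategy.
    """
    if y is None:
        if X.labels is None:
            raise ValueError("training labels required")
        y = np.asarray(X.labels)
    subspaces = select_subspaces(
        X, y, selectors, epsilon=epsilon, knn=knn, k=k, seed=seed
    )
    members = []
    for sub in subspaces:
        if hyperparams is None:
            hp = grid_search_svm(
                X.values[:, sub.indices], y, C_grid, gamma_grid, inner_folds, seed
            )
        else:
            hp = hyperparams
        members.append(train_subspace_svm(X, y, sub, hp, seed=seed))
    return EnsemblePredictor(
        members=members,
        propensity_table=propensity_table,
        window=window,
    )


def save_model(model: EnsemblePredictor, path) -> None:
    """Persist an ensemble as a versioned joblib archive."""
    payload = {
        "version": ARCHIVE_VERSION,
        "window": model.window,
        "threshold": model.threshold,
        "threshold_strategy": model.threshold_strategy,
        "propensity_table": model.propensity_table,
        "members": [
            {
                "indices": m.subspace.indices,
                "method": m.subspace.method,
                "hyperparams": m.hyperparams,
                "training_meta": m.training_meta,
                "svm": m.svm,
            }
            for m in model.members
        ],
    }
    joblib.dump(payload, Path(path))


def load_model(path) -> EnsemblePredictor:
    payload = joblib.load(Path(path))
    version = payload.get("version")
    if version != ARCHIVE_VERSION:
        raise ValueError(
            f"model archive version {version!r} incompatible with {ARCHIVE_VERSION!r}"
        )
    members = [
        SubspaceModel(
            subspace=FeatureSubspace(indices=m["indices"], method=m["method"]),
            svm=m["svm"],
            hyperparams=tuple(m["hyperparams"]),
            training_meta=m["training_meta"],
        )
        for m in payload["members"]
    ]
    return EnsemblePredictor(
        members=members,
        threshold=payload["threshold"],
        threshold_strategy=payload["threshold_strategy"],
        propensity_table=payload["propensity_table"],
        window=payload["window"],
    )
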