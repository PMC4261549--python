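"""Evaluation metrics, threshold strategies, and cross-validation.

Metrics: sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP),
accuracy Acc = (TP+TN)/total (all reported as percentages), the Matthews
correlation coefficient, and ROC AUC.

Two threshold-selection strategies are provided: *balanced* picks the
threshold that equalizes Sn and Sp as nearly as possible, *maxmcc* picks
the MCC-maximizing threshold.  Both scan the midpoints between adjacent
distinct scores plus the boundary values {0, 1} — a finite candidate set
that realizes every achievable confusion table.

Cross-validation can partition at the residue level (residues of one
sequence may straddle folds, which leaks within-sequence similarity into
training) or the sequence level (whole sequences are held out; the
leakage-free protocol).  Test scores are pooled over the folds and a
single global threshold is applied, so one confusion table summarizes
the whole run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score

from .ensemble import classify, train_ensemble
from .features import (
    FeatureMatrix,
    build_feature_matrix,
    compute_binding_propensities,
)
from .io import ProfileMatrix, ProteinRecord, SSProbMatrix


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(calls: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    calls = np.asarray(calls).astype(int)
    truth = np.asarray(truth).astype(int)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have equal length")
    return ConfusionCounts(
        TP=int(((calls == 1) & (truth == 1)).sum()),
        FP=int(((calls == 1) & (truth == 0)).sum()),
        TN=int(((calls == 0) & (truth == 0)).sum()),
        FN=int(((calls == 0) & (truth == 1)).sum()),
    )


def sensitivity(c: ConfusionCounts) -> float:
    """TP/(TP+FN) as a percentage; NaN when no positives exist."""
    den = c.TP + c.FN
    return 100.0 * c.TP / den if den else math.nan


def specificity(c: ConfusionCounts) -> float:
    """TN/(TN+FP) as a percentage; NaN when no negatives exist."""
    den = c.TN + c.FP
    return 100.0 * c.TN / den if den else math.nan


def accuracy(c: ConfusionCounts) -> float:
    """(TP+TN)/total as a percentage; NaN on an empty table."""
    return 100.0 * (c.TP + c.TN) / c.total if c.total else math.nan


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    den = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if den == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / math.sqrt(den)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding, the convention of printed metric tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Rank-statistic AUC, ties counting one half; NaN if single-class."""
    truth = np.asarray(truth).astype(int)
    if len(np.unique(truth)) < 2:
        return math.nan
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


@dataclass
class EvaluationReport:
    counts: ConfusionCounts
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float
    threshold: float
    strategy: str
    cv_level: str = "none"

    def to_dict(self) -> Dict[str, object]:
        return {
            "TP": self.counts.TP,
            "FP": self.counts.FP,
            "TN": self.counts.TN,
            "FN": self.counts.FN,
            "Sn": self.sn,
            "Sp": self.sp,
            "Acc": self.acc,
            "MCC": self.mcc,
            "AUC": self.auc,
            "threshold": self.threshold,
            "strategy": self.strategy,
            "cv_level": self.cv_level,
        }


def report_at_threshold(
    scores: np.ndarray,
    truth: np.ndarray,
    T: float,
    strategy: str = "fixed",
    cv_level: str = "none",
) -> EvaluationReport:
    """Evaluate binary calls ``score > T`` against the truth labels."""
    c = confusion(classify(scores, T), truth)
    return EvaluationReport(
        counts=c,
        sn=sensitivity(c),
        sp=specificity(c),
        acc=accuracy(c),
        mcc=mcc(c),
        auc=roc_auc(scores, truth),
        threshold=float(T),
        strategy=strategy,
        cv_level=cv_level,
    )


def threshold_candidates(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores, plus {0, 1}."""
    u = np.unique(np.asarray(scores, dtype=float))
    mids = (u[:-1] + u[1:]) / 2.0
    return np.unique(np.concatenate([[0.0], mids, [1.0]]))


def _scan_confusions(
    scores: np.ndarray, truth: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized TP/FP over every candidate threshold (call = score > T)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    cands = threshold_candidates(scores)
    pos = np.sort(scores[truth == 1])
    neg = np.sort(scores[truth == 0])
    # residues called positive have score strictly above T
    tp = len(pos) - np.searchsorted(pos, cands, side="right")
    fp = len(neg) - np.searchsorted(neg, cands, side="right")
    return cands, tp, fp


def balanced_threshold(
    scores: np.ndarray, truth: np.ndarray, cv_level: str = "none"
) -> Tuple[float, EvaluationReport]:
    """Threshold minimizing |Sn - Sp|; ties go to the smaller threshold."""
    truth = np.asarray(truth).astype(int)
    nP, nN = int((truth == 1).sum()), int((truth == 0).sum())
    if nP == 0 or nN == 0:
        raise ValueError("both classes must be present")
    cands, tp, fp = _scan_confusions(scores, truth)
    sn = tp / nP
    sp = (nN - fp) / nN
    best = int(np.argmin(np.abs(sn - sp)))  # first (smallest T) on ties
    T = float(cands[best])
    return T, report_at_threshold(scores, truth, T, strategy="balanced", cv_level=cv_level)


def maxmcc_threshold(
    scores: np.ndarray, truth: np.ndarray, cv_level: str = "none"
) -> Tuple[float, EvaluationReport]:
    """Threshold maximizing the MCC; ties go to the smaller threshold."""
    truth = np.asarray(truth).astype(int)
    nP, nN = int((truth == 1).sum()), int((truth == 0).sum())
    if nP == 0 or nN == 0:
        raise ValueError("both classes must be present")
    cands, tp, fp = _scan_confusions(scores, truth)
    fn = nP - tp
    tn = nN - fp
    num = tp * tn - fp * fn
    den = np.sqrt(
        (tp + fp).astype(float) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mccs = np.where(den > 0, num / den, 0.0)
    best = int(np.argmax(mccs))  # first (smallest T) on ties
    T = float(cands[best])
    return T, report_at_threshold(scores, truth, T, strategy="maxmcc", cv_level=cv_level)


THRESHOLD_STRATEGIES = {
    "balanced": balanced_threshold,
    "maxmcc": maxmcc_threshold,
}


@dataclass
class CVPlan:
    """A k-fold partition at the residue or sequence level.

    ``assignment`` maps each sequence id to an integer fold per residue;
    at sequence level every residue of a sequence shares one fold.
    """

    level: str
    k: int
    assignment: Dict[str, np.ndarray]
    seed: int

    def fold_of(self, rid: str, pos: int) -> int:
        return int(self.assignment[rid][pos])


def make_cv_folds(
    records: Sequence[ProteinRecord], level: str, k: int = 5, seed: int = 0
) -> CVPlan:
    """Randomly partition residues or sequences into k near-equal folds."""
    if level not in ("residue", "sequence"):
        raise ValueError(f"level must be 'residue' or 'sequence', got {level!r}")
    if k < 2:
        raise ValueError("k must be >= 2")
    records = list(records)
    rng = np.random.default_rng(seed)
    assignment: Dict[str, np.ndarray] = {}
    if level == "sequence":
        n = len(records)
        if n < k:
            raise ValueError(f"{n} sequences cannot form {k} folds")
        folds = np.concatenate([np.arange(k)] * (n // k + 1))[:n]
        folds = folds[rng.permutation(n)]
        for rec, f in zip(records, folds):
            assignment[rec.id] = np.full(len(rec), f, dtype=int)
    else:
        total = sum(len(r) for r in records)
        if total < k:
            raise ValueError(f"{total} residues cannot form {k} folds")
        folds = np.concatenate([np.arange(k)] * (total // k + 1))[:total]
        folds = folds[rng.permutation(total)]
        offset = 0
        for rec in records:
            assignment[rec.id] = folds[offset : offset + len(rec)].copy()
            offset += len(rec)
    return CVPlan(level=level, k=k, assignment=assignment, seed=seed)


@dataclass
class CVResult:
    """Pooled out-of-fold scores from one cross-validation run."""

    scores: np.ndarray
    truth: np.ndarray
    member_scores: np.ndarray  # n_members x M, pooled like `scores`
    residue_index: List[Tuple[str, int]]
    plan: CVPlan
    selector_names: Tuple[str, ...]

    def report(self, strategy: str = "balanced", fixed_T: Optional[float] = None) -> EvaluationReport:
        if strategy == "fixed":
            if fixed_T is None:
                raise ValueError("fixed strategy needs a threshold")
            return report_at_threshold(
                self.scores, self.truth, fixed_T, strategy="fixed", cv_level=self.plan.level
            )
        _, rep = THRESHOLD_STRATEGIES[strategy](self.scores, self.truth, cv_level=self.plan.level)
        return rep


def plan_is_valid(records: Sequence[ProteinRecord], plan: CVPlan) -> bool:
    """True iff every fold's training and test split contains both classes.

    Cross-validation preconditions can fail by chance on small, heavily
    imbalanced datasets (a fold may draw no binding residues); callers
    that generate their own data can check cheaply and redraw.
    """
    truth = np.concatenate([rec.labels for rec in records]).astype(int)
    folds = np.concatenate([plan.assignment[rec.id] for rec in records])
    for fold in range(plan.k):
        for mask in (folds == fold, folds != fold):
            if len(np.unique(truth[mask])) < 2:
                return False
    return True


def cross_validate(
    records: Sequence[ProteinRecord],
    profiles: Mapping[str, ProfileMatrix],
    ss: Mapping[str, SSProbMatrix],
    selectors: Sequence[str],
    plan: CVPlan,
    seed: int = 0,
    *,
    window: int = 17,
    epsilon: float = 0.5,
    knn: int = 5,
    k: Optional[int] = None,
    hyperparams: Optional[Tuple[float, float]] = None,
    C_grid=None,
    gamma_grid=None,
    inner_folds: int = 3,
    vitamin_class: str = "generic",
) -> CVResult:
    """Run k-fold CV; every residue is scored exactly once, out of fold.

    Inside each fold the propensity table, the selectors, and the SVMs
    see training residues only.  Per-fold inner hyperparameter tuning is
    used unless fixed ``hyperparams`` are given.
    """
    from .ensemble import DEFAULT_C_GRID, DEFAULT_GAMMA_GRID

    records = list(records)
    for rec in records:
        if rec.labels is None:
            raise ValueError(f"record {rec.id!r} carries no labels")
    if C_grid is None:
        C_grid = DEFAULT_C_GRID
    if gamma_grid is None:
        gamma_grid = DEFAULT_GAMMA_GRID

    index = [(rec.id, pos) for rec in records for pos in range(len(rec))]
    row_of = {key: i for i, key in enumerate(index)}
    M = len(index)
    truth = np.concatenate([rec.labels for rec in records]).astype(np.int8)
    fold_of_row = np.array(
        [plan.fold_of(rid, pos) for rid, pos in index], dtype=int
    )

    pooled = np.full(M, np.nan)
    member_pooled: Optional[np.ndarray] = None

    for fold in range(plan.k):
        test_mask = fold_of_row == fold
        train_mask = ~test_mask
        y_train = truth[train_mask]
        if len(np.unique(y_train)) < 2 or len(np.unique(truth[test_mask])) < 2:
            raise ValueError(f"fold {fold}: a split is missing one of the classes")

        # propensities from training residues only
        train_records = []
        for rec in records:
            in_train = plan.assignment[rec.id] != fold
            if in_train.any():
                sub_seq = "".join(a for a, m in zip(rec.sequence, in_train) if m)
                sub_lab = rec.labels[in_train]
                train_records.append(
                    ProteinRecord(id=rec.id, sequence=sub_seq, labels=sub_lab)
                )
        prop = compute_binding_propensities(train_records, vitamin_class=vitamin_class)

        full = build_feature_matrix(records, profiles, ss, prop, W=window)
        X_train = FeatureMatrix(
            values=full.values[train_mask],
            block_spans=full.block_spans,
            residue_index=[index[i] for i in np.flatnonzero(train_mask)],
            labels=y_train,
        )
        model = train_ensemble(
            X_train,
            selectors=selectors,
            seed=seed,
            epsilon=epsilon,
            knn=knn,
            k=k,
            hyperparams=hyperparams,
            C_grid=C_grid,
            gamma_grid=gamma_grid,
            inner_folds=inner_folds,
            propensity_table=prop,
            window=window,
        )
        mscores = model.member_scores(full.values[test_mask])
        if member_pooled is None:
            member_pooled = np.full((mscores.shape[0], M), np.nan)
        member_pooled[:, test_mask] = mscores
        pooled[test_mask] = mscores.mean(axis=0)

    assert not np.isnan(pooled).any()
    return CVResult(
        scores=pooled,
        truth=truth,
        member_scores=member_pooled,
        residue_index=index,
        plan=plan,
        selector_names=tuple(selectors),
    )


def run_cv(
    records: Sequence[ProteinRecord],
    profiles: Mapping[str, ProfileMatrix],
    ss: Mapping[str, SSProbMatrix],
    selectors: Sequence[str],
    plan: CVPlan,
    strategy: str = "balanced",
    seed: int = 0,
    **kwargs,
) -> EvaluationReport:
    """Cross-validate and report with one global pooled threshold."""
    result = cross_validate(records, profiles, ss, selectors, plan, seed, **kwargs)
    return result.report(strategy=strategy)
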