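import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitabind import (
    ConfusionCounts,
    GeneratorConfig,
    accuracy,
    balanced_threshold,
    confusion,
    cross_validate,
    generate_dataset,
    make_cv_folds,
    maxmcc_threshold,
    mcc,
    roc_auc,
    sensitivity,
    specificity,
)
from vitabind.evaluation import report_at_threshold, threshold_candidates


class TestConfusion:
    def test_all_correct_positive(self):
        c = confusion([1, 1, 1], [1, 1, 1])
        assert (c.TP, c.FP, c.TN, c.FN) == (3, 0, 0, 0)

    def test_all_wrong(self):
        c = confusion([1, 0], [0, 1])
        assert (c.TP, c.TN) == (0, 0) and (c.FP, c.FN) == (1, 1)

    def test_hand_count(self):
        c = confusion([1, 0, 1, 0], [1, 1, 0, 0])
        assert (c.TP, c.FN, c.FP, c.TN) == (1, 1, 1, 1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestMetrics:
    def test_benchmark_confusion_row(self):
        # counts from a residue-level CV evaluation of a vitamin-binding
        # benchmark (imbalanced ~1:20); metrics recomputed independently
        c = ConfusionCounts(TP=2342, TN=49797, FP=12325, FN=674)
        assert sensitivity(c) == pytest.approx(77.65, abs=0.005)
        assert specificity(c) == pytest.approx(80.16, abs=0.005)
        assert accuracy(c) == pytest.approx(80.04, abs=0.005)
        assert mcc(c) == pytest.approx(0.29, abs=0.005)

    def test_perfect_prediction_mcc(self):
        assert mcc(ConfusionCounts(TP=1, TN=1, FP=0, FN=0)) == 1.0

    def test_mcc_zero_denominator_convention(self):
        assert mcc(ConfusionCounts(TP=0, TN=5, FP=0, FN=0)) == 0.0

    def test_undefined_marker_not_exception(self):
        c = ConfusionCounts(TP=0, FP=3, TN=2, FN=0)  # no positives
        assert math.isnan(sensitivity(c))
        assert specificity(c) == pytest.approx(40.0)


class TestRocAuc:
    def test_perfect_and_inverted(self):
        truth = [0, 0, 1, 1]
        assert roc_auc([0.1, 0.2, 0.8, 0.9], truth) == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], truth) == 0.0

    def test_known_value(self):
        assert roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_single_class_undefined(self):
        assert math.isnan(roc_auc([0.5, 0.6], [1, 1]))

    @given(st.data())
    @settings(deadline=None, max_examples=50)
    def test_matches_pair_counting_oracle(self, data):
        n = data.draw(st.integers(4, 12))
        scores = data.draw(
            st.lists(st.floats(0, 1, width=32), min_size=n, max_size=n)
        )
        truth = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda t: 0 < sum(t) < len(t)
            )
        )
        pairs = wins = 0
        for si, ti in zip(scores, truth):
            for sj, tj in zip(scores, truth):
                if ti == 1 and tj == 0:
                    pairs += 1
                    wins += 1.0 if si > sj else 0.5 if si == sj else 0.0
        assert roc_auc(scores, truth) == pytest.approx(wins / pairs)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(50)
        truth = rng.integers(0, 2, 50)
        a = roc_auc(scores, truth)
        b = roc_auc(1 / (1 + np.exp(-7 * scores + 2)), truth)
        assert a == pytest.approx(b)


def exhaustive_scan(scores, truth, objective):
    best_T, best_val = None, None
    for T in threshold_candidates(scores):
        calls = (np.asarray(scores) > T).astype(int)
        val = objective(confusion(calls, truth))
        if best_val is None or val > best_val + 1e-15:
            best_T, best_val = T, val
    return best_T, best_val


class TestThresholdStrategies:
    def test_balanced_on_separable_scores(self):
        T, rep = balanced_threshold([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1])
        assert 0.4 < T < 0.6 or rep.sn == rep.sp
        assert rep.sn == pytest.approx(rep.sp) == pytest.approx(100.0)

    def test_maxmcc_on_separable_scores(self):
        _, rep = maxmcc_threshold([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1])
        assert rep.mcc == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_balanced_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(200)
        truth = rng.integers(0, 2, 200)
        T, rep = balanced_threshold(scores, truth)
        _, best_gap = exhaustive_scan(
            scores, truth, lambda c: -abs(sensitivity(c) - specificity(c))
        )
        assert -abs(rep.sn - rep.sp) == pytest.approx(best_gap)

    @pytest.mark.parametrize("seed", range(5))
    def test_maxmcc_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(200)
        truth = rng.integers(0, 2, 200)
        T, rep = maxmcc_threshold(scores, truth)
        _, best = exhaustive_scan(scores, truth, mcc)
        assert rep.mcc == pytest.approx(best)
        # argmax contract at the returned threshold
        for T_alt in threshold_candidates(scores)[::7]:
            alt = report_at_threshold(scores, truth, T_alt)
            assert rep.mcc >= alt.mcc - 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            maxmcc_threshold([0.2, 0.8], [1, 1])

    def test_marginals_constant_across_thresholds(self, rng):
        scores = rng.random(60)
        truth = rng.integers(0, 2, 60)
        for T in (0.1, 0.5, 0.9):
            c = confusion((scores > T).astype(int), truth)
            assert c.TP + c.FN == truth.sum()
            assert c.TN + c.FP == (1 - truth).sum()


class TestCvFolds:
    def test_sequence_level_even_split(self, small_dataset):
        recs = small_dataset.records  # 8 sequences
        plan = make_cv_folds(recs, "sequence", k=4, seed=0)
        per_fold = {f: 0 for f in range(4)}
        for rec in recs:
            folds = set(plan.assignment[rec.id].tolist())
            assert len(folds) == 1  # whole sequence in one fold
            per_fold[folds.pop()] += 1
        assert all(v == 2 for v in per_fold.values())

    def test_residue_level_even_split(self, small_dataset):
        recs = small_dataset.records
        total = sum(len(r) for r in recs)
        plan = make_cv_folds(recs, "residue", k=5, seed=0)
        counts = np.bincount(
            np.concatenate([plan.assignment[r.id] for r in recs]), minlength=5
        )
        assert counts.max() - counts.min() <= 1
        assert counts.sum() == total

    def test_reproducible_from_seed(self, small_dataset):
        p1 = make_cv_folds(small_dataset.records, "residue", k=5, seed=9)
        p2 = make_cv_folds(small_dataset.records, "residue", k=5, seed=9)
        for rid in p1.assignment:
            np.testing.assert_array_equal(p1.assignment[rid], p2.assignment[rid])

    def test_too_few_units_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            make_cv_folds(small_dataset.records, "sequence", k=50, seed=0)


@pytest.fixture(scope="module")
def cv_run():
    cfg = GeneratorConfig(n_sequences=8, length_range=(20, 30), seed=2)
    ds = generate_dataset(cfg)
    plan = make_cv_folds(ds.records, "sequence", k=2, seed=2)
    res = cross_validate(
        ds.records, ds.profiles, ds.ss, ("fisher",), plan, seed=2,
        hyperparams=(8.0, 2 ** -5), k=408,
    )
    return ds, plan, res


class TestCrossValidate:
    def test_every_residue_scored_once(self, cv_run):
        ds, _, res = cv_run
        assert len(res.scores) == sum(len(r) for r in ds.records)
        assert np.isfinite(res.scores).all()
        assert ((res.scores >= 0) & (res.scores <= 1)).all()

    def test_report_counts_tie_to_dataset(self, cv_run):
        ds, _, res = cv_run
        rep = res.report("maxmcc")
        n_pos = int(sum(r.labels.sum() for r in ds.records))
        assert rep.counts.TP + rep.counts.FN == n_pos
        assert rep.cv_level == "sequence"

    def test_deterministic(self, cv_run):
        ds, plan, res = cv_run
        res2 = cross_validate(
            ds.records, ds.profiles, ds.ss, ("fisher",), plan, seed=2,
            hyperparams=(8.0, 2 ** -5), k=408,
        )
        np.testing.assert_array_equal(res.scores, res2.scores)
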