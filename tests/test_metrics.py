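"""Diagnostic metrics, ROC/AUC dual-route agreement, threshold rule, CV plan."""

import numpy as np
import pytest

from lnrads import (
    ConfusionMatrix,
    aggregate_runs,
    auc_mann_whitney,
    confusion_from_predictions,
    grouped_roc_auc,
    make_cv_plan,
    metrics_from_cm,
    roc_and_auc,
    sad_classify,
    select_threshold,
)

# per-level benign / malignant counts of the published cohort
NEG_COUNTS = [21, 28, 57, 53, 12, 1]
POS_COUNTS = [0, 0, 1, 30, 77, 118]


def _pair_count_auc(neg_counts, pos_counts):
    """Exhaustive concordant/tied pair counting over the grouped data."""
    concordant = tied = 0
    for i, npos in enumerate(pos_counts):
        for j, nneg in enumerate(neg_counts):
            if i > j:
                concordant += npos * nneg
            elif i == j:
                tied += npos * nneg
    return (concordant + 0.5 * tied) / (sum(pos_counts) * sum(neg_counts))


class TestConfusionMetrics:
    def test_published_baseline_row(self):
        ms = metrics_from_cm(ConfusionMatrix(tp=138, tn=147, fp=25, fn=88))
        assert ms.accuracy == pytest.approx(0.7161, abs=5e-5)
        assert ms.specificity == pytest.approx(0.8547, abs=5e-5)
        assert ms.sensitivity == pytest.approx(0.6106, abs=5e-5)
        assert ms.precision == pytest.approx(0.8466, abs=5e-5)
        assert ms.f1 == pytest.approx(0.7095, abs=5e-5)
        assert round(ms.accuracy, 2) == 0.72

    def test_perfect_and_symmetric_cases(self):
        ms = metrics_from_cm(ConfusionMatrix(tp=10, tn=10, fp=0, fn=0))
        assert all(v == 1.0 for v in vars(ms).values())
        ms = metrics_from_cm(ConfusionMatrix(tp=1, tn=1, fp=1, fn=1))
        assert all(v == 0.5 for v in vars(ms).values())

    def test_zero_denominator_flagged_undefined(self):
        ms = metrics_from_cm(ConfusionMatrix(tp=0, tn=5, fp=0, fn=0))
        assert ms.precision is None and ms.sensitivity is None and ms.f1 is None
        assert ms.accuracy == 1.0
        with pytest.raises(ValueError):
            metrics_from_cm(ConfusionMatrix(tp=0, tn=0, fp=0, fn=0))


class TestROC:
    def test_perfect_separation_and_all_ties(self):
        assert roc_and_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])[1] == 1.0
        assert roc_and_auc([5.0] * 6, [0, 0, 0, 1, 1, 1])[1] == 0.5

    def test_grouped_ordinal_auc_matches_pair_count_oracle(self):
        oracle = _pair_count_auc(NEG_COUNTS, POS_COUNTS)
        assert oracle == pytest.approx(36994.5 / 38872, abs=1e-15)
        assert grouped_roc_auc(NEG_COUNTS, POS_COUNTS) == pytest.approx(oracle, abs=1e-12)

    def test_trapezoid_equals_mann_whitney_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(4, 30)
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = np.zeros(n, bool)
            labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = True
            if labels.all() or not labels.any():
                continue
            _, auc = roc_and_auc(scores, labels)
            assert auc == pytest.approx(auc_mann_whitney(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(size=60)
        labels = rng.uniform(size=60) < 0.4
        pts, auc = roc_and_auc(scores, labels)
        pts2, auc2 = roc_and_auc(np.exp(3 * scores) - 1, labels)
        assert auc2 == pytest.approx(auc, abs=1e-12)
        assert np.allclose(pts, pts2)

    def test_roc_points_monotone_from_origin_to_one(self):
        rng = np.random.default_rng(2)
        pts, _ = roc_and_auc(rng.uniform(size=40), rng.uniform(size=40) < 0.5)
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_and_auc([1, 2, 3], [1, 1, 1])


class TestThreshold:
    def test_two_point_instance(self):
        assert select_threshold([0.1, 0.9], [False, True]) == pytest.approx(0.5)

    def test_all_scores_equal_takes_low_sentinel(self):
        thr = select_threshold([0.5] * 6, [0, 1, 0, 1, 1, 0])
        assert thr < 0.5  # everything classified positive under the tie rule

    def test_matches_brute_force_sweep(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            scores = np.round(rng.uniform(size=20), 2)
            labels = rng.uniform(size=20) < 0.5
            if labels.all() or not labels.any():
                continue
            distinct = np.unique(scores)
            cands = np.concatenate(
                [[distinct[0] - 1], (distinct[:-1] + distinct[1:]) / 2, [distinct[-1] + 1]]
            )
            js = []
            for c in cands:
                tp = fp = 0
                for s, lab in zip(scores, labels):
                    if s > c:
                        tp += lab
                        fp += not lab
                js.append(tp / labels.sum() - fp / (~labels).sum())
            js = np.asarray(js)
            chosen = select_threshold(scores, labels)
            # the chosen threshold attains the optimal J, and is the smallest
            # candidate attaining it
            j_chosen = js[np.argmin(np.abs(cands - chosen))]
            assert j_chosen == js.max()
            assert chosen == cands[js == js.max()].min()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([0.2, 0.8], [True, True])


class TestSADRule:
    def test_strict_boundary_convention(self):
        assert sad_classify(12.0) is True
        assert sad_classify(10.0) is False
        assert sad_classify(9.9) is False
        with pytest.raises(ValueError):
            sad_classify(0.0)

    def test_reproduces_calibrated_operating_point(self, big_cohort):
        sad = np.array([r.sad_mm for r in big_cohort])
        y = np.array([r.malignant for r in big_cohort])
        cm = confusion_from_predictions(sad_classify(sad), y)
        ms = metrics_from_cm(cm)
        assert ms.sensitivity == pytest.approx(0.6106, abs=0.01)
        assert 1 - ms.specificity == pytest.approx(0.1453, abs=0.01)


class TestCVPlan:
    def test_stratification_bounds(self):
        rng = np.random.default_rng(4)
        y = np.zeros(398, bool)
        y[:226] = True
        y = rng.permutation(y)
        plan = make_cv_plan(y, k=5, repeats=10, seed=0)
        for r in range(10):
            for f in range(5):
                _, test_idx = plan.split(r, f)
                pos = int(y[test_idx].sum())
                assert pos in (45, 46)
                prevalence = y[test_idx].mean()
                assert abs(prevalence - y.mean()) <= 1 / len(test_idx)

    def test_partition_and_determinism(self):
        y = np.arange(40) % 2 == 0
        p1 = make_cv_plan(y, k=5, repeats=3, seed=9)
        p2 = make_cv_plan(y, k=5, repeats=3, seed=9)
        assert np.array_equal(p1.assignments, p2.assignments)
        for r in range(3):
            folds = [set(p1.split(r, f)[1]) for f in range(5)]
            assert set().union(*folds) == set(range(40))
            assert sum(len(f) for f in folds) == 40

    def test_too_few_members_rejected(self):
        with pytest.raises(ValueError):
            make_cv_plan([True, False, True, True], k=5)
        with pytest.raises(ValueError):
            make_cv_plan([True] * 10 + [False] * 10, k=1)


class TestAggregate:
    def test_identical_runs_and_mean(self):
        runs = [{"acc": 0.7, "curve": np.array([1.0, 2.0])},
                {"acc": 0.9, "curve": np.array([3.0, 4.0])}]
        means, stds = aggregate_runs(runs)
        assert means["acc"] == pytest.approx(0.8)
        assert np.allclose(means["curve"], [2.0, 3.0])
        assert stds["acc"] == pytest.approx(0.1)
        # mean of curves commutes with epoch selection
        assert means["curve"][1] == pytest.approx(np.mean([2.0, 4.0]))

    def test_mismatched_curves_rejected(self):
        with pytest.raises(ValueError):
            aggregate_runs([{"c": np.zeros(3)}, {"c": np.zeros(4)}])
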