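"""ROC machinery, cross-validated posteriors and the bootstrap."""

import numpy as np
import pandas as pd
import pytest

from pathint.diagnostics import (
    ClassifierSpec,
    bootstrap_roc,
    crossval_posteriors,
    roc_from_scores,
    threshold_report,
)


def mann_whitney_auc(scores, labels):
    """Brute-force pairwise oracle: P(pos > neg) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocFromScores:
    def test_tied_example(self):
        scores = np.array([1.0, 2.0, 3.0, 0.0, 1.0, 2.0])
        labels = np.array([1, 1, 1, 0, 0, 0])
        assert roc_from_scores(scores, labels).auc == pytest.approx(7 / 9)

    def test_disjoint_ranges(self):
        r = roc_from_scores(np.array([3.0, 4.0, 1.0, 2.0]), np.array([1, 1, 0, 0]))
        assert r.auc == 1.0
        assert r.sensitivity_at_opt == 1.0
        assert r.specificity_at_opt == 1.0

    def test_full_ties(self):
        r = roc_from_scores(np.ones(10), np.r_[np.ones(5), np.zeros(5)].astype(int))
        assert r.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_from_scores(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_equals_mann_whitney_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = np.zeros(n, int)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            r = roc_from_scores(scores, labels)
            assert r.auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=50)
        labels = (rng.random(50) < 0.4).astype(int)
        labels[:2] = [0, 1]
        a = roc_from_scores(scores, labels).auc
        b = roc_from_scores(np.exp(scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_label_swap_mirrors_auc(self, rng):
        scores = rng.normal(size=40)
        labels = np.r_[np.ones(15), np.zeros(25)].astype(int)
        a = roc_from_scores(scores, labels).auc
        b = roc_from_scores(scores, 1 - labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_curve_monotone(self, rng):
        r = roc_from_scores(np.round(rng.normal(size=60), 1),
                            (rng.random(60) < 0.5).astype(int))
        assert (np.diff(r.fpr) >= 0).all()
        assert (np.diff(r.tpr) >= 0).all()
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)


def _features(rng, n1=14, n2=12, gap=0.0):
    y = np.r_[np.zeros(n1), np.ones(n2)].astype(int)
    return (
        pd.DataFrame(
            {
                "mean_abs_error": rng.normal(1.4, 0.3, n1 + n2) + gap * y,
                "age": rng.normal(71, 8, n1 + n2),
                "sex01": rng.integers(0, 2, n1 + n2),
                "education": rng.normal(14, 3, n1 + n2),
            }
        ),
        y,
    )


class TestCrossvalPosteriors:
    def test_perfect_separation(self, rng):
        X, y = _features(rng, gap=5.0)
        post, folds = crossval_posteriors(X, y, ClassifierSpec(rng_seed=1))
        assert np.all((post > 0.5) == (y == 1))
        assert set(folds) == set(range(10))

    def test_deterministic_per_seed(self, rng):
        X, y = _features(rng, gap=1.0)
        p1, f1 = crossval_posteriors(X, y, ClassifierSpec(rng_seed=3))
        p2, f2 = crossval_posteriors(X, y, ClassifierSpec(rng_seed=3))
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(f1, f2)

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(8)
        X, y = _features(rng, n1=30, n2=30, gap=1.0)
        aucs = []
        for rep in range(30):
            ys = rng.permutation(y)
            post, _ = crossval_posteriors(X, ys, ClassifierSpec(rng_seed=rep))
            aucs.append(roc_from_scores(post, ys).auc)
        aucs = np.asarray(aucs)
        sem = aucs.std(ddof=1) / np.sqrt(len(aucs))
        assert abs(aucs.mean() - 0.5) < 2 * sem + 0.02

    def test_k_exceeding_class_size_rejected(self, rng):
        X, y = _features(rng, n1=5, n2=30)
        with pytest.raises(ValueError, match="k_folds"):
            crossval_posteriors(X, y, ClassifierSpec(k_folds=10))

    def test_lda_variant_runs(self, rng):
        X, y = _features(rng, gap=1.0)
        post, _ = crossval_posteriors(X, y, ClassifierSpec(model="lda"))
        assert np.all((0 <= post) & (post <= 1))


class TestThresholdReport:
    def test_separating_threshold(self):
        sens, spec = threshold_report(
            np.array([2.0, 2.5, 1.0, 1.5]), np.array([1, 1, 0, 0]), 1.96
        )
        assert (sens, spec) == (1.0, 1.0)

    def test_inverted_case(self):
        sens, spec = threshold_report(np.array([1.0, 2.0]), np.array([1, 0]), 1.5)
        assert (sens, spec) == (0.0, 0.0)

    def test_counting_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 40))
            e = np.round(rng.uniform(0.5, 3.0, n), 2)
            y = np.zeros(n, int)
            y[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if y.sum() in (0, n):
                continue
            thr = float(rng.uniform(0.5, 3.0))
            sens, spec = threshold_report(e, y, thr)
            assert sens == sum(1 for v in e[y == 1] if v >= thr) / (y == 1).sum()
            assert spec == sum(1 for v in e[y == 0] if v < thr) / (y == 0).sum()

    def test_label_swap_exchanges_rates(self, rng):
        e = rng.uniform(0.5, 3.0, 30)
        y = (rng.random(30) < 0.5).astype(int)
        y[:2] = [0, 1]
        sens, spec = threshold_report(e, y, 1.5)
        sens2, spec2 = threshold_report(e, 1 - y, 1.5)
        assert sens2 == pytest.approx(1 - spec)
        assert spec2 == pytest.approx(1 - sens)


class TestBootstrapRoc:
    def test_zero_variance_features_collapse_ci(self, rng):
        """Constant features carry no discriminative signal: the bootstrap
        interval collapses to a point.  The point AUC itself can sit off 0.5
        because out-of-fold intercepts vary slightly with fold composition —
        tiny prior differences are the only ordering left, a cross-validation
        artifact rather than signal — so only a loose bound applies to it."""
        X, y = _features(rng)
        X[:] = 1.0
        r = bootstrap_roc(X, y, ClassifierSpec(bootstrap_reps=40, rng_seed=5))
        assert r.ci_high - r.ci_low < 0.05
        assert abs(r.auc - 0.5) < 0.25

    def test_small_sample_ci_is_typically_wide(self):
        """At the study's 12-vs-14 sample size a classifier with true AUC near
        0.9 keeps a wide bootstrap interval in the typical replicate."""
        widths = []
        for rep in range(5):
            rng = np.random.default_rng(100 + rep)
            X, y = _features(rng, gap=0.55)  # true AUC ~ 0.9
            r = bootstrap_roc(X, y, ClassifierSpec(bootstrap_reps=120, rng_seed=rep))
            assert r.ci_low <= r.auc <= r.ci_high
            widths.append(r.ci_high - r.ci_low)
        assert np.median(widths) > 0.15

    def test_ci_narrows_with_sample_size(self):
        rng = np.random.default_rng(12)
        widths = []
        for scale in (1, 8):
            X, y = _features(rng, n1=14 * scale, n2=12 * scale, gap=0.55)
            r = bootstrap_roc(X, y, ClassifierSpec(bootstrap_reps=60, rng_seed=scale))
            widths.append(r.ci_high - r.ci_low)
        assert widths[1] < widths[0]
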