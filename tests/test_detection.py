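import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from fidnav.detection import (
    bootstrap_632,
    confusion,
    dichotomize,
    roc,
    spearman,
    weighted_kappa,
    youden_optimal,
)

# the worked 4-subject example: positives score [0.35, 0.8], negatives [0.1, 0.4]
SCORES4 = np.array([0.35, 0.8, 0.1, 0.4])
LABELS4 = np.array([True, True, False, False])


def grid_youden(scores, labels):
    """Exhaustive grid-search oracle for the Youden optimum."""
    best_j, best_c = -np.inf, None
    for c in sorted(np.unique(scores)) + [np.inf]:
        called = scores >= c
        se = np.sum(called & labels) / labels.sum()
        sp = np.sum(~called & ~labels) / (~labels).sum()
        j = se + sp - 1
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return best_j, best_c


class TestConfusion:
    def test_perfect_separation(self):
        c = confusion(np.array([0.9, 0.8, 0.1, 0.2]), LABELS4, 0.5)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 2, 0)
        assert c.se == 1.0 and c.sp == 1.0

    def test_zero_threshold_calls_everything(self):
        c = confusion(SCORES4, LABELS4, 0.0)
        assert c.se == 1.0 and c.sp == 0.0

    def test_enumeration_oracle(self):
        c = confusion(SCORES4, LABELS4, 0.35)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 1, 0)
        assert c.se == 1.0 and c.sp == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="positive and one negative"):
            confusion(np.ones(3), np.array([True, True, True]), 0.5)


class TestRoc:
    def test_perfect_separation_auc_one(self):
        r = roc(np.array([3.0, 4.0, 1.0, 2.0]), LABELS4)
        assert r.auc == pytest.approx(1.0)

    def test_identical_scores_auc_half(self):
        r = roc(np.ones(6), np.array([True, True, True, False, False, False]))
        assert r.auc == pytest.approx(0.5)

    def test_pair_counting_oracle(self):
        # 3 of 4 pos>neg pairs concordant, 0 ties -> AUC 0.75
        assert roc(SCORES4, LABELS4).auc == pytest.approx(0.75)

    def test_sensitivity_non_increasing_in_threshold(self, rng):
        scores = rng.normal(size=40)
        labels = rng.uniform(size=40) < 0.4
        if labels.all() or not labels.any():
            labels[:2] = [True, False]
        r = roc(scores, labels)
        order = np.argsort(r.thresholds)
        assert np.all(np.diff(r.se_curve[order]) <= 1e-12)

    @pytest.mark.parametrize("seed", range(25))
    def test_auc_equals_mann_whitney_statistic(self, seed):
        """Trapezoidal ROC AUC == tie-corrected Mann-Whitney U / (n1*n0)."""
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 50)
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.uniform(size=n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        u = stats.mannwhitneyu(scores[labels], scores[~labels]).statistic
        expected = u / (labels.sum() * (~labels).sum())
        assert roc(scores, labels).auc == pytest.approx(expected)
        assert roc(scores, labels).auc == pytest.approx(roc_auc_score(labels, scores))


class TestYouden:
    def test_perfect_separation(self):
        j, c = youden_optimal(roc(np.array([3.0, 4.0, 1.0, 2.0]), LABELS4))
        assert j == pytest.approx(1.0)
        assert 2.0 < c <= 3.0

    def test_identical_distributions_give_zero(self):
        j, _ = youden_optimal(roc(np.ones(4), LABELS4))
        assert j == pytest.approx(0.0)

    def test_tie_broken_toward_smaller_threshold(self):
        j, c = youden_optimal(roc(SCORES4, LABELS4))
        assert j == pytest.approx(0.5)
        assert c == pytest.approx(0.35)  # tie with c=0.8 broken low

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed + 1000)
        scores = np.round(rng.normal(size=30), 1)
        labels = rng.uniform(size=30) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        j, _ = youden_optimal(roc(scores, labels))
        j_grid, _ = grid_youden(scores, labels)
        assert j == pytest.approx(j_grid)


class TestBootstrap632:
    def test_well_separated_classes_perfect_accuracy(self, rng):
        # gap >> spread: each class concentrated on one value, so every
        # replicate threshold sits in the gap and out-of-bag calls are exact
        scores = np.concatenate([np.full(10, 100.0), np.zeros(20)])
        labels = np.arange(30) < 10
        res = bootstrap_632(scores, labels, b=50, seed=3)
        assert res.se_632 == pytest.approx(1.0)
        assert res.sp_632 == pytest.approx(1.0)
        assert res.auc_mean == pytest.approx(1.0)

    def test_blend_arithmetic(self):
        # 0.368 * 1.0 + 0.632 * 0.8 = 0.8736
        assert 0.368 * 1.0 + 0.632 * 0.8 == pytest.approx(0.8736)

    def test_fixed_point_of_blend(self):
        # when resubstitution and out-of-bag accuracy agree, the blend returns it
        scores = np.concatenate([np.full(8, 5.0), np.zeros(12)])
        labels = np.arange(20) < 8
        res = bootstrap_632(scores, labels, b=25, seed=9)
        assert res.se_632 == 1.0 and res.sp_632 == 1.0

    def test_deterministic_for_seed(self, rng):
        scores = rng.normal(size=30)
        labels = np.arange(30) < 12
        a = bootstrap_632(scores, labels, b=40, seed=7)
        b = bootstrap_632(scores, labels, b=40, seed=7)
        assert a.se_632 == b.se_632 and a.auc_mean == b.auc_mean

    def test_full_sample_threshold_reported(self):
        res = bootstrap_632(SCORES4 * 10, LABELS4, b=5, seed=0)
        _, c = youden_optimal(roc(SCORES4 * 10, LABELS4))
        assert res.threshold == pytest.approx(c)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_632(np.ones(5), np.zeros(5, dtype=bool), b=3, seed=0)


class TestMonotoneInvariance:
    def test_auc_j_rho_unchanged_by_monotone_transform(self, rng):
        scores = rng.uniform(0.1, 5.0, size=40)
        grades = rng.integers(1, 6, size=40)
        labels = grades <= 2
        if labels.all() or not labels.any():
            labels[:2] = [True, False]
        transformed = np.log(scores)
        assert roc(scores, labels).auc == pytest.approx(roc(transformed, labels).auc)
        j1, _ = youden_optimal(roc(scores, labels))
        j2, _ = youden_optimal(roc(transformed, labels))
        assert j1 == pytest.approx(j2)
        assert spearman(scores, grades)[0] == pytest.approx(spearman(transformed, grades)[0])


class TestSpearman:
    def test_monotone_gives_one(self):
        assert spearman(np.arange(10.0), np.arange(10.0))[0] == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self):
        assert spearman(np.arange(10.0), -np.arange(10.0))[0] == pytest.approx(-1.0)

    def test_rank_formula_oracle(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 12/60 = 0.8
        rho, _ = spearman(np.array([1.0, 2, 3, 4]), np.array([1.0, 3, 2, 4]))
        assert rho == pytest.approx(0.8)

    def test_constant_input_warns_returns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, _ = spearman(np.ones(5), np.arange(5.0))
        assert rho == 0.0


class TestWeightedKappa:
    def test_identical_ratings(self):
        g = np.array([1, 2, 3, 4, 5, 3, 2])
        k, (lo, hi) = weighted_kappa(g, g, n_boot=100, seed=1)
        assert k == pytest.approx(1.0)
        assert hi <= 1.0

    def test_independent_ratings_near_zero(self, rng):
        a = rng.integers(1, 6, size=600)
        b = rng.integers(1, 6, size=600)
        k, _ = weighted_kappa(a, b, n_boot=50, seed=2)
        assert abs(k) < 0.1

    def test_contingency_table_oracle(self):
        # 2x2 table [[20, 5], [5, 20]]: hand-computed observed vs expected
        a = np.array([1] * 25 + [2] * 25)
        b = np.array([1] * 20 + [2] * 5 + [1] * 5 + [2] * 20)
        po = 40 / 50
        pe = (25 / 50) * (25 / 50) + (25 / 50) * (25 / 50)
        expected = (po - pe) / (1 - pe)
        k, _ = weighted_kappa(a, b, n_boot=50, seed=3)
        assert k == pytest.approx(expected)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            weighted_kappa(np.array([1, 2]), np.array([1, 2, 3]))


class TestDichotomize:
    def test_both_schemes(self):
        grades = np.array([1, 2, 3, 4, 5])
        np.testing.assert_array_equal(dichotomize(grades, "12v345"), [1, 1, 0, 0, 0])
        np.testing.assert_array_equal(dichotomize(grades, "123v45"), [1, 1, 1, 0, 0])

    def test_bad_grade_rejected(self):
        with pytest.raises(ValueError):
            dichotomize(np.array([0, 3]), "12v345")
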