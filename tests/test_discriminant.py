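import numpy as np
import pytest

from perfcad.comparison import ScoreMap
from perfcad.discriminant import (
    DiscriminantThresholds,
    classify_subject,
    count_hypoperfused,
    counts_over_grid,
    default_tb_grid,
    default_tw_grid,
    grid_search,
    svm_classify,
)
from perfcad.synth import generate_counts


class TestThresholds:
    def test_bounds(self):
        DiscriminantThresholds(t_w=0.86, t_b=200)
        with pytest.raises(ValueError):
            DiscriminantThresholds(t_w=0.4, t_b=0)
        with pytest.raises(ValueError):
            DiscriminantThresholds(t_w=0.9, t_b=-1)


class TestCounting:
    def test_inclusive_boundary(self):
        P = ScoreMap(np.array([0.9, 0.86, 0.5, 0.99]), kind="posterior")
        assert count_hypoperfused(P, 0.86) == 3

    def test_all_zero(self):
        P = ScoreMap(np.zeros(10), kind="posterior")
        assert count_hypoperfused(P, 0.86) == 0

    def test_requires_posterior_kind(self):
        L = ScoreMap(np.array([0.9]), kind="likelihood")
        with pytest.raises(ValueError, match="posterior"):
            count_hypoperfused(L, 0.86)

    def test_non_increasing_in_tw(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, 500)
        counts = [count_hypoperfused(vals, tw) for tw in default_tw_grid()]
        assert counts == sorted(counts, reverse=True)

    def test_counts_over_grid_matches_direct(self):
        rng = np.random.default_rng(1)
        posts = rng.uniform(0, 1, (5, 200))
        grid = default_tw_grid()
        counts = counts_over_grid(posts, grid)
        for i, tw in enumerate(grid):
            for s in range(5):
                assert counts[i, s] == (posts[s] >= tw).sum()


class TestClassify:
    def test_above_threshold_is_ad(self):
        assert classify_subject(250, 200) == "AD"

    def test_boundary_is_hc(self):
        assert classify_subject(200, 200) == "HC"  # strict inequality

    def test_zero_count_always_hc(self):
        for tb in [0, 10, 5000]:
            assert classify_subject(0, tb) == "HC"


class TestGridSearch:
    def _surface_from_counts(self, counts, is_ad, tw_grid=None, tb_grid=None):
        tw_grid = default_tw_grid() if tw_grid is None else tw_grid
        counts_by_tw = np.tile(counts, (len(tw_grid), 1))
        return grid_search(counts_by_tw, is_ad, tw_grid, tb_grid)

    def test_small_instance_tiebreak(self):
        # HC {10, 20}, AD {300, 400}: zero error for t_b in {50..250};
        # smallest t_b wins after the t_w preference
        counts = np.array([10, 20, 300, 400])
        is_ad = np.array([False, False, True, True])
        surf = self._surface_from_counts(counts, is_ad)
        assert surf.chosen.t_b == 50
        assert surf.misclassification[surf.chosen_index] == 0.0
        assert surf.chosen.t_w == 0.5  # conservative cutoff preferred on ties

    def test_tb_zero_everything_ad(self):
        counts = np.array([5, 8, 300, 400])
        is_ad = np.array([False, False, True, True])
        surf = self._surface_from_counts(counts, is_ad)
        i0 = int(np.where(surf.tb_grid == 0)[0][0])
        assert surf.sensitivity[0, i0] == 1.0
        assert surf.specificity[0, i0] == 0.0

    def test_tb_above_max_count(self):
        counts = np.array([5, 8, 300, 400])
        is_ad = np.array([False, False, True, True])
        surf = self._surface_from_counts(counts, is_ad)
        assert surf.sensitivity[0, -1] == 0.0
        assert surf.specificity[0, -1] == 1.0

    def test_single_class_fatal(self):
        counts = np.array([5, 8])
        with pytest.raises(ValueError, match="both classes"):
            self._surface_from_counts(counts, np.array([False, False]))

    def test_misclassification_consistent_with_confusion(self):
        rng = np.random.default_rng(2)
        posts = rng.uniform(0, 1, (12, 100))
        is_ad = np.arange(12) < 5
        tw_grid = default_tw_grid()
        tb_grid = np.arange(0, 101, 10)
        counts = counts_over_grid(posts, tw_grid)
        surf = grid_search(counts, is_ad, tw_grid, tb_grid)
        np.testing.assert_allclose(
            surf.misclassification,
            ((1 - surf.sensitivity) * is_ad.sum() + (1 - surf.specificity) * (~is_ad).sum())
            / len(is_ad),
            atol=1e-12,
        )

    def test_surface_monotone_in_tb(self):
        rng = np.random.default_rng(3)
        posts = rng.uniform(0, 1, (10, 300))
        is_ad = np.arange(10) < 4
        counts = counts_over_grid(posts, default_tw_grid())
        surf = grid_search(counts, is_ad)
        assert (np.diff(surf.sensitivity, axis=1) <= 0).all()
        assert (np.diff(surf.specificity, axis=1) >= 0).all()

    def test_threshold_recovery_poisson(self):
        # HC ~ Poisson(50), AD ~ Poisson(500): separated with prob ~ 1
        counts, is_ad = generate_counts(20, 20, 50.0, 500.0, seed=0)
        assert counts[~is_ad].max() < counts[is_ad].min()
        surf = self._surface_from_counts(counts, is_ad)
        assert surf.misclassification[surf.chosen_index] == 0.0
        assert counts[~is_ad].max() <= surf.chosen.t_b < counts[is_ad].min()

    def test_equal_rates_near_chance(self):
        counts, is_ad = generate_counts(40, 40, 200.0, 200.0, seed=5)
        surf = self._surface_from_counts(counts, is_ad)
        # even the optimal training cell cannot do much better than chance
        assert surf.misclassification[surf.chosen_index] > 0.2


class TestLOO:
    def test_planted_cohort_rates(self, planted_loo):
        assert planted_loo.sensitivity >= 0.9
        assert planted_loo.specificity >= 0.9

    def test_null_cohort_near_chance(self, null_loo):
        assert 0.3 <= null_loo.sensitivity <= 0.7
        assert 0.3 <= null_loo.specificity <= 0.7

    def test_fold_thresholds_concentrate(self, planted_loo):
        # computed on the default planted cohort: the modal pair is chosen
        # in a majority of folds (t_b varies with the extreme HC subject)
        assert planted_loo.modal_fraction >= 0.5
        assert planted_loo.modal_thresholds.t_w == 0.5

    def test_fold_bookkeeping(self, planted_loo, planted):
        assert len(planted_loo.folds) == planted.cohort.n_subjects
        ids = [f.subject_id for f in planted_loo.folds]
        assert ids == planted.cohort.subject_ids

    def test_pooled_rates_match_folds(self, planted_loo):
        folds = planted_loo.folds
        n_ad = sum(f.true_group.startswith("AD") for f in folds)
        tp = sum(
            f.predicted == "AD" for f in folds if f.true_group.startswith("AD")
        )
        assert planted_loo.sensitivity == pytest.approx(tp / n_ad)


class TestSVM:
    def test_separable_counts(self):
        rng = np.random.default_rng(0)
        n = 30
        X = rng.normal(0, 1, (n, 40))
        X[n // 2 :] += 2.0
        is_ad = np.arange(n) >= n // 2
        acc, sens, spec = svm_classify(X, is_ad, gamma=1.0 / 40)
        assert acc >= 0.9

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (40, 30))
        is_ad = rng.permutation(np.arange(40) < 20)
        acc, _, _ = svm_classify(X, is_ad)
        assert 0.2 <= acc <= 0.8

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (20, 25))
        is_ad = np.arange(20) < 10
        assert svm_classify(X, is_ad) == svm_classify(X, is_ad)

    def test_planted_beats_chance(self, planted_loo, planted):
        is_ad = np.array([g.startswith("AD") for g in planted.cohort.groups])
        acc, sens, spec = svm_classify(planted_loo.posteriors_matrix(), is_ad)
        assert acc >= 0.8
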