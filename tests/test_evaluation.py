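"""ROC convex hull, threshold sweep, Monte-Carlo CV, Cohen's kappa."""

import numpy as np
import pytest

from vesseltort.evaluation import (
    OperatingPoint,
    cohen_kappa,
    monte_carlo_cv,
    roc_convex_hull,
    threshold_sweep,
)


class TestROCConvexHull:
    def test_single_point_trapezoid(self):
        hull = roc_convex_hull([OperatingPoint(0.8, 0.8)])
        assert hull.auc == pytest.approx(0.8, abs=1e-12)
        np.testing.assert_allclose(hull.vertices, [[0, 0], [0.2, 0.8], [1, 1]])

    def test_perfect_point_gives_unit_auc(self):
        hull = roc_convex_hull([OperatingPoint(1.0, 1.0), OperatingPoint(0.5, 0.5)])
        assert hull.auc == pytest.approx(1.0, abs=1e-12)

    def test_corners_only_chance_diagonal(self):
        hull = roc_convex_hull([OperatingPoint(0.0, 1.0), OperatingPoint(1.0, 0.0)])
        assert hull.auc == pytest.approx(0.5, abs=1e-12)

    def test_hull_dominates_raw_polyline(self, rng):
        points = [OperatingPoint(s, p) for s, p in rng.random((20, 2))]
        hull = roc_convex_hull(points)
        raw = sorted([(p.fpr, p.tpr) for p in points] + [(0, 0), (1, 1)])
        raw_auc = np.trapezoid([t for _, t in raw], [f for f, _ in raw])
        assert hull.auc >= raw_auc - 1e-12
        # every point lies on or below the hull
        for p in points:
            assert hull.interpolate(np.array([p.fpr]))[0] >= p.tpr - 1e-12

    def test_duplicates_do_not_change_auc(self, rng):
        points = [OperatingPoint(s, p) for s, p in rng.random((10, 2))]
        assert roc_convex_hull(points + points).auc == pytest.approx(
            roc_convex_hull(points).auc, abs=1e-12
        )


class TestThresholdSweep:
    def test_interleaved_scores_enumeration(self):
        scores = [(0.1, 0), (0.2, 1), (0.3, 0), (0.4, 1)]
        points = threshold_sweep(scores)
        assert len(points) == 5
        # raw trapezoid over the operating points equals the rank AUC (0.75:
        # 3 of 4 pos/neg pairs correctly ordered); the hull dominates it
        raw = sorted({(p.fpr, p.tpr) for p in points})
        raw_auc = np.trapezoid([t for _, t in raw], [f for f, _ in raw])
        assert raw_auc == pytest.approx(0.75, abs=1e-12)
        assert roc_convex_hull(points).auc == pytest.approx(0.875, abs=1e-12)

    def test_separable_scores_contain_perfect_point(self):
        scores = [(0.1, 0), (0.2, 0), (0.8, 1), (0.9, 1)]
        points = threshold_sweep(scores)
        assert any(p.sensitivity == 1.0 and p.specificity == 1.0 for p in points)

    def test_identical_scores_trivial_points_only(self):
        points = threshold_sweep([(0.5, 0), (0.5, 1), (0.5, 0)])
        assert len(points) == 2
        ops = {(p.sensitivity, p.specificity) for p in points}
        assert ops == {(1.0, 0.0), (0.0, 1.0)}

    def test_hull_auc_at_least_rank_auc(self, rng):
        scores = rng.random(30)
        labels = (rng.random(30) < 0.5).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        points = threshold_sweep(list(zip(scores, labels)))
        hull_auc = roc_convex_hull(points).auc
        # Mann-Whitney rank AUC
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        greater = (pos[:, None] > neg[None, :]).mean()
        ties = (pos[:, None] == neg[None, :]).mean()
        assert hull_auc >= greater + ties / 2 - 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep([(0.1, 1), (0.2, 1)])


class TestMonteCarloCV:
    def _tables_labels(self):
        from test_fit import toy_tables

        taus = [[0.0001 * (i + 1)] if i % 2 == 0 else [0.01 * (i + 1)] for i in range(20)]
        return toy_tables(taus), [i % 2 for i in range(20)]

    def test_sweep_mode_separable_is_perfect(self):
        tables, labels = self._tables_labels()
        cv = monte_carlo_cv(tables, labels, mode="sweep", seed=4)
        assert cv.mean == pytest.approx(1.0)
        assert cv.std == pytest.approx(0.0)
        assert len(cv.aucs) == 10

    def test_same_seed_reproducible(self):
        tables, labels = self._tables_labels()
        kw = dict(mode="fit", n_repeats=3, seed=9,
                  fit_kwargs=dict(pop_size=20, max_generations=10))
        cv1 = monte_carlo_cv(tables, labels, **kw)
        cv2 = monte_carlo_cv(tables, labels, **kw)
        assert cv1.aucs == cv2.aucs and cv1.seeds == cv2.seeds

    def test_too_small_dataset_rejected(self):
        tables, labels = self._tables_labels()
        with pytest.raises(ValueError):
            monte_carlo_cv(tables[:4], labels[:4], mode="sweep")


class TestCohenKappa:
    def test_identical_lists(self):
        assert cohen_kappa([1, 0, 1, 1], [1, 0, 1, 1]) == 1.0

    def test_exact_complements_balanced(self):
        a = [1, 1, 0, 0]
        b = [0, 0, 1, 1]
        assert cohen_kappa(a, b) == pytest.approx(-1.0)

    def test_hand_computed_table(self):
        a = (1, 1, 0, 0, 1, 0, 1, 0, 1, 1)
        b = (1, 0, 0, 0, 1, 0, 1, 1, 1, 1)
        # p_o = 0.8, p_e = 0.6*0.6 + 0.4*0.4 = 0.52 -> kappa = 0.28/0.48
        assert cohen_kappa(a, b) == pytest.approx(0.28 / 0.48)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(20):
            a = rng.integers(0, 2, size=30)
            b = rng.integers(0, 2, size=30)
            expected = cohen_kappa_score(a, b)
            if np.isnan(expected):
                continue
            assert cohen_kappa(a, b) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa([1, 0], [1])
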