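"""Composite score, evaluator, cross-validation, PCA and grid search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import LinearRegression

from algaeopt.model_eval import (DEFAULT_GRIDS, DEFAULT_ROSTER, MetricSet,
                                 ModelCandidate, cross_validate, evaluate,
                                 grid_search, leaderboard_frame,
                                 make_model_pipeline, mean_metrics,
                                 pca_reduce, w_new)
from algaeopt.reference import PUBLISHED_LEADERBOARD

finite = st.floats(min_value=-5, max_value=5, allow_nan=False)
positive = st.floats(min_value=1e-6, max_value=10, allow_nan=False)


class TestWNew:
    @pytest.mark.parametrize("family", sorted(PUBLISHED_LEADERBOARD))
    def test_reproduces_published_composite_scores(self, family):
        r2t, r2v, mae, rmse, mse, reported = PUBLISHED_LEADERBOARD[family]
        assert w_new(r2t, r2v, mae, rmse, mse) == pytest.approx(
            reported, abs=0.005)

    def test_zero_skill_gives_zero(self):
        assert w_new(0.0, 0.0, 0.2, 0.3, 0.1) == 0.0

    def test_negative_skill_gives_zero(self):
        assert w_new(-0.5, -0.1, 0.2, 0.3, 0.1) == 0.0

    def test_perfect_model_limit(self):
        assert w_new(1.0, 1.0, 0.0, 0.0, 0.0) == 1.0

    def test_zero_error_without_skill_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            w_new(0.0, 0.0, 0.0, 0.0, 0.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            w_new(np.nan, 0.5, 0.1, 0.1, 0.01)

    @given(r2t=finite, r2v=finite, mae=positive, rmse=positive, mse=positive)
    @settings(max_examples=300, derandomize=True)
    def test_bounded_on_all_finite_inputs(self, r2t, r2v, mae, rmse, mse):
        assert 0.0 <= w_new(r2t, r2v, mae, rmse, mse) <= 1.0

    def test_strictly_decreasing_in_total_error(self):
        # fixed R2 sum and gap, growing error
        scores = [w_new(0.7, 0.5, err / 3, err / 3, err / 3)
                  for err in np.linspace(0.1, 2.0, 15)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_strictly_increasing_in_skill_sum(self):
        # fixed gap 0.1 and fixed errors, growing R2 sum
        scores = [w_new(s / 2 + 0.05, s / 2 - 0.05, 0.1, 0.15, 0.02)
                  for s in np.linspace(0.2, 1.9, 15)]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_strictly_decreasing_in_train_val_gap(self):
        # fixed sum 1.2 and errors, growing |R2t - R2v|
        scores = [w_new(0.6 + d / 2, 0.6 - d / 2, 0.1, 0.15, 0.02)
                  for d in np.linspace(0.0, 0.95, 15)]
        assert all(a > b for a, b in zip(scores, scores[1:]))


class TestEvaluate:
    def test_perfect_predictor(self):
        X = np.arange(10, dtype=float)[:, None]
        y = 2 * X.ravel() + 1
        model = LinearRegression().fit(X, y)
        m = evaluate(model, (X, y), (X, y))
        assert m.r2_train == pytest.approx(1.0)
        assert m.r2_val == pytest.approx(1.0)
        assert m.mae == pytest.approx(0.0, abs=1e-9)
        assert m.w_new == 1.0

    def test_train_mean_predictor_has_zero_train_r2(self):
        class MeanModel:
            def fit(self, X, y):
                self.mean_ = np.mean(y)
                return self

            def predict(self, X):
                return np.full(len(X), self.mean_)

        X = np.arange(8, dtype=float)[:, None]
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0, 5.0, 7.0])
        m = evaluate(MeanModel().fit(X, y), (X, y), (X, y))
        assert m.r2_train == pytest.approx(0.0, abs=1e-12)

    def test_five_point_hand_computation(self):
        # y_val = [1,2,3,4,5], predictions [1.5, 2, 2.5, 4, 5.5]:
        # residuals [-.5, 0, .5, 0, -.5]; MAE = 1.5/5 = 0.3;
        # MSE = 0.75/5 = 0.15; RMSE = sqrt(0.15);
        # SS_res = 0.75, SS_tot = 10 -> r2_val = 0.925
        class Fixed:
            def predict(self, X):
                return np.asarray([1.5, 2.0, 2.5, 4.0, 5.5])

        X = np.arange(5, dtype=float)[:, None]
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = evaluate(Fixed(), (X, y), (X, y))
        assert m.mae == pytest.approx(0.3)
        assert m.mse == pytest.approx(0.15)
        assert m.rmse == pytest.approx(np.sqrt(0.15))
        assert m.r2_val == pytest.approx(1 - 0.75 / 10)
        assert m.rmse ** 2 == pytest.approx(m.mse, abs=1e-9)

    def test_zero_variance_validation_target_rejected(self):
        X = np.arange(4, dtype=float)[:, None]
        with pytest.raises(ValueError, match="variance"):
            evaluate(LinearRegression().fit(X, X.ravel()),
                     (X, X.ravel()), (X, np.ones(4)))


class TestCrossValidate:
    def test_fold_sizes(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 4))
        y = X @ [1, 2, 0, 0.5] + rng.normal(0, 0.1, 300)
        folds = cross_validate(ModelCandidate("linear"), X, y, k=5, seed=1)
        assert len(folds) == 5

    def test_same_seed_identical_folds(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 3))
        y = X @ [1, -1, 2] + rng.normal(0, 0.1, 60)
        a = cross_validate(ModelCandidate("decision_tree"), X, y, k=5, seed=9)
        b = cross_validate(ModelCandidate("decision_tree"), X, y, k=5, seed=9)
        assert [m.as_dict() for m in a] == [m.as_dict() for m in b]

    def test_k_exceeding_n_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            cross_validate(ModelCandidate("linear"), X, np.arange(3.0), k=5)

    def test_reduction_refit_inside_folds(self):
        # a pca branch must not crash and must reproduce deterministically
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 8))
        y = X[:, 0] * 3 + rng.normal(0, 0.1, 80)
        cand = ModelCandidate("linear", (), ("pca", 5))
        a = cross_validate(cand, X, y, k=2, seed=0)
        b = cross_validate(cand, X, y, k=2, seed=0)
        assert [m.w_new for m in a] == [m.w_new for m in b]


class TestPcaReduce:
    def test_identity_covariance_equal_fractions(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(4000, 2))
        X = (X - X.mean(0)) / X.std(0)
        _, frac = pca_reduce(X, k=2)
        assert frac[0] == pytest.approx(0.5, abs=0.05)
        assert frac[1] == pytest.approx(0.5, abs=0.05)

    def test_duplicated_column_concentrates_variance(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=300)
        X = np.column_stack([a, a])
        _, frac = pca_reduce(X, k=2)
        assert frac[0] == pytest.approx(1.0, abs=1e-9)

    def test_fractions_match_covariance_eigendecomposition(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 8)) @ rng.normal(size=(8, 8))
        _, frac = pca_reduce(X, k=8)
        cov = np.cov(X, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(frac, eig / eig.sum(), atol=1e-10)
        assert frac.sum() == pytest.approx(1.0)

    def test_threshold_mode_smallest_k(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(200, 3))
        X = np.column_stack([base, base + rng.normal(0, 0.01, (200, 3))])
        reduced, frac = pca_reduce(X, variance_threshold=0.85)
        cum = np.cumsum(frac)
        assert cum[-1] >= 0.85
        assert reduced.shape[1] == len(frac)
        if len(frac) > 1:
            assert cum[-2] < 0.85

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            pca_reduce(np.zeros((10, 3)), k=4)


@pytest.fixture(scope="module")
def xy():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(120, 5))
    y = X @ [2, -1, 0.5, 0, 0] + rng.normal(0, 0.2, 120)
    return X, y


class TestGridSearch:
    def test_single_candidate_returned(self, xy):
        res = grid_search(("linear",), {"linear": {}}, *xy, k=3, seed=0)
        assert res.best.family == "linear"
        assert len(res.leaderboard) == 1
        assert len(res.fold_metrics) == 3

    def test_dominant_candidate_selected(self, xy):
        # on clean linear data the linear model dominates a 1-neighbour
        # KNN on every metric; exhaustive scoring confirms the argmax
        X, y = xy
        grids = {"linear": {}, "knn": {"n_neighbors": [1]}}
        res = grid_search(("knn", "linear"), grids, X, y, k=3, seed=0)
        scores = {c.family: m.w_new for c, m in res.leaderboard}
        assert res.best.family == max(scores, key=scores.get)
        assert res.best.family == "linear"

    def test_leaderboard_size_is_grid_times_branches(self, xy):
        grids = {"linear": {}, "decision_tree": {"max_depth": [2, 4, 6]}}
        res = grid_search(("linear", "decision_tree"), grids, *xy, k=2,
                          seed=0, branches=("none", ("pca", 3)))
        assert len(res.leaderboard) == (1 + 3) * 2

    def test_empty_roster_rejected(self, xy):
        with pytest.raises(ValueError):
            grid_search((), {}, *xy)

    def test_unknown_family_rejected(self, xy):
        with pytest.raises(KeyError):
            grid_search(("perceptron9000",), {}, *xy)

    def test_seed_determinism(self, xy):
        args = (("linear", "decision_tree"),
                {"linear": {}, "decision_tree": {"max_depth": [3]}})
        a = grid_search(*args, *xy, k=3, seed=5)
        b = grid_search(*args, *xy, k=3, seed=5)
        assert a.best == b.best
        assert a.holdout_metrics.as_dict() == b.holdout_metrics.as_dict()

    def test_leaderboard_frame_layout(self, xy):
        res = grid_search(("linear", "knn"),
                          {"linear": {}, "knn": {"n_neighbors": [3, 5]}},
                          *xy, k=2, seed=0)
        frame = leaderboard_frame(res.leaderboard)
        assert list(frame.index) == ["r2_train", "r2_val", "mae", "rmse",
                                     "mse", "w_new"]
        assert set(frame.columns) == {"linear", "knn"}


def test_mean_metrics_recomputes_composite():
    a = MetricSet(0.8, 0.6, 0.1, 0.2, 0.04, w_new(0.8, 0.6, 0.1, 0.2, 0.04))
    b = MetricSet(0.6, 0.4, 0.3, 0.4, 0.16, w_new(0.6, 0.4, 0.3, 0.4, 0.16))
    mm = mean_metrics([a, b])
    assert mm.r2_train == pytest.approx(0.7)
    assert mm.w_new == pytest.approx(w_new(0.7, 0.5, 0.2, 0.3, 0.1))


def test_default_roster_matches_declared_families():
    assert len(DEFAULT_ROSTER) == 9
    for fam in DEFAULT_ROSTER:
        assert fam in DEFAULT_GRIDS
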