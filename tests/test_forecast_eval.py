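import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sensopt.forecast_eval as fe
from sensopt import BoostParams, fit_boosted, rmse, tune
from sensopt.node_model import SupervisedFrame
from sensopt.preprocess import SplitSpec


def make_frame(X: np.ndarray, y: np.ndarray) -> SupervisedFrame:
    cols = [f"f{i}" for i in range(X.shape[1])]
    return SupervisedFrame(
        X=pd.DataFrame(X, columns=cols), y=pd.Series(y, name="y"), k=1,
        target_name="y",
    )


class TestRmse:
    def test_identical_series_zero(self):
        assert rmse([1, 2], [1, 2]) == 0.0

    def test_pythagorean_example(self):
        assert rmse([0, 0], [3, 4]) == pytest.approx(3.5355339059)

    def test_matches_brute_force_loop(self, rng):
        a = rng.normal(size=200)
        p = rng.normal(size=200)
        acc = 0.0
        for x, y in zip(a, p):
            acc += (x - y) ** 2
        assert rmse(a, p) == pytest.approx((acc / 200) ** 0.5, rel=1e-12)

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([1], [1, 2])
        with pytest.raises(ValueError):
            rmse([], [])

    @given(c=st.floats(min_value=-50, max_value=50))
    @settings(deadline=None)
    def test_scale_equivariance(self, c):
        a = np.array([1.0, -2.0, 0.5])
        p = np.array([0.0, 1.0, 2.0])
        assert rmse(c * a, c * p) == pytest.approx(abs(c) * rmse(a, p), abs=1e-9)


class TestBoostParams:
    @pytest.mark.parametrize(
        "kwargs",
        [{"n_estimators": 0}, {"learning_rate": 0.0}, {"learning_rate": 1.5},
         {"max_depth": 0}],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BoostParams(**kwargs)

    def test_defaults_follow_tuned_operating_point(self):
        p = BoostParams()
        assert p.n_estimators == 1000 and p.learning_rate == 0.01


class TestFitBoosted:
    def test_constant_target_perfectly_predicted(self, rng):
        X = rng.normal(size=(40, 2))
        frame = make_frame(X, np.full(40, 3.0))
        result = fit_boosted(frame, BoostParams(n_estimators=5, learning_rate=0.5))
        assert result.val_rmse == pytest.approx(0.0, abs=1e-12)

    def test_representable_function_learned_to_high_accuracy(self, rng):
        # target equals a threshold function of the first feature
        X = rng.uniform(size=(300, 2))
        y = (X[:, 0] > 0.5).astype(float)
        frame = make_frame(X, y)
        result = fit_boosted(
            frame, BoostParams(n_estimators=300, learning_rate=0.3, max_depth=3)
        )
        assert result.val_rmse < 0.05

    def test_single_stump_equals_brute_force_stump_fit(self, rng):
        """One stage, depth 1, learning rate 1 reduces to mean + best stump."""
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        frame = make_frame(X, y)
        split = SplitSpec(0.7)
        result = fit_boosted(
            frame,
            BoostParams(n_estimators=1, learning_rate=1.0, max_depth=1),
            split=split,
            scale=False,
        )
        b = split.boundary(12)
        X_tr, y_tr = X[:b], y[:b]
        X_va, y_va = X[b:], y[b:]
        base = y_tr.mean()
        resid = y_tr - base

        best = (np.inf, None)
        for j in range(X_tr.shape[1]):
            order = np.sort(np.unique(X_tr[:, j]))
            for lo, hi in zip(order[:-1], order[1:]):
                thr = (lo + hi) / 2
                left = resid[X_tr[:, j] <= thr]
                right = resid[X_tr[:, j] > thr]
                sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
                if sse < best[0]:
                    best = (sse, (j, thr, left.mean(), right.mean()))
        j, thr, lmean, rmean = best[1]
        pred_va = base + np.where(X_va[:, j] <= thr, lmean, rmean)
        assert result.val_rmse == pytest.approx(rmse(y_va, pred_va), rel=1e-12)

    def test_training_rmse_non_increasing_in_stages(self, rng):
        X = rng.normal(size=(100, 3))
        y = X[:, 0] + 0.3 * rng.normal(size=100)
        frame = make_frame(X, y)
        rmses = [
            fit_boosted(frame, BoostParams(n_estimators=n, learning_rate=0.1)).train_rmse
            for n in (10, 50, 200)
        ]
        assert rmses[0] >= rmses[1] >= rmses[2]

    def test_refit_is_bit_identical(self, rng):
        X = rng.normal(size=(60, 2))
        y = rng.normal(size=60)
        frame = make_frame(X, y)
        params = BoostParams(n_estimators=20, learning_rate=0.1)
        a = fit_boosted(frame, params)
        b = fit_boosted(frame, params)
        assert a.val_rmse == b.val_rmse and a.train_rmse == b.train_rmse

    def test_empty_frame_rejected(self):
        frame = make_frame(np.empty((0, 1)), np.empty(0))
        with pytest.raises(ValueError):
            fit_boosted(frame)


class TestTune:
    @pytest.fixture()
    def smooth_frame(self, rng):
        t = np.linspace(0, 8 * np.pi, 240)
        y = np.sin(t) + 0.05 * rng.normal(size=240)
        X = np.column_stack([np.sin(t - 0.1), np.cos(t - 0.1)])
        return make_frame(X, y)

    def test_single_point_space_returned(self, smooth_frame):
        space = {"n_estimators": [50], "learning_rate": [0.1], "max_depth": [3]}
        params = tune(smooth_frame, space)
        assert (params.n_estimators, params.learning_rate, params.max_depth) == (50, 0.1, 3)

    def test_good_point_beats_deliberately_bad_point(self, smooth_frame):
        space = {
            "n_estimators": [10, 500],
            "learning_rate": [0.9, 0.05],
            "max_depth": [7, 3],
        }
        params = tune(smooth_frame, space)
        assert params.n_estimators == 500
        assert params.learning_rate == 0.05

    def test_grid_evaluates_every_depth(self, smooth_frame, monkeypatch):
        evaluated = []
        real = fe.fit_boosted

        def spy(frame, params, **kw):
            evaluated.append(params.max_depth)
            return real(frame, params, **kw)

        monkeypatch.setattr(fe, "fit_boosted", spy)
        tune(
            smooth_frame,
            {"n_estimators": [20], "learning_rate": [0.1],
             "max_depth": [2, 3, 4, 5, 6, 7]},
        )
        assert sorted(evaluated) == [2, 3, 4, 5, 6, 7]

    def test_ties_break_toward_cheaper_model(self, rng):
        X = rng.normal(size=(30, 1))
        frame = make_frame(X, np.zeros(30))  # every combo scores 0
        params = tune(
            frame,
            {"n_estimators": [100, 10], "learning_rate": [0.1], "max_depth": [5, 2]},
        )
        assert params.n_estimators == 10 and params.max_depth == 2

    def test_random_strategy_is_seeded_and_bounded(self, smooth_frame, monkeypatch):
        calls = []
        real = fe.fit_boosted

        def spy(frame, params, **kw):
            calls.append(params)
            return real(frame, params, **kw)

        monkeypatch.setattr(fe, "fit_boosted", spy)
        space = {"n_estimators": [10, 20, 40], "learning_rate": [0.1, 0.3],
                 "max_depth": [2, 3]}
        a = tune(smooth_frame, space, strategy="random", n_iter=5, rng_seed=3)
        n_first = len(calls)
        b = tune(smooth_frame, space, strategy="random", n_iter=5, rng_seed=3)
        assert n_first == 5 and a == b

    def test_empty_space_rejected(self, smooth_frame):
        with pytest.raises(ValueError):
            tune(smooth_frame, {})
        with pytest.raises(ValueError):
            tune(smooth_frame, {"max_depth": []})
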