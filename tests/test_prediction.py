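import math

import numpy as np
import pandas as pd
import pytest

import meadev as md
from meadev.features import FEATURES
from meadev.prediction import importance_strategies, train_test_split_dishes


def toy_trajectories(n_dishes=20, seed=0, drop_late_for=()):
    """Minimal trajectory table with intervals 0 and 2 for every dish."""
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_dishes):
        dish = f"d{d:02d}"
        base = rng.normal(size=len(FEATURES))
        for interval in (0, 2):
            if interval == 2 and dish in drop_late_for:
                continue
            vals = base + interval * 0.5 + rng.normal(0, 0.05, len(FEATURES))
            rows.append({"dish": dish, "interval": interval,
                         **dict(zip(FEATURES, vals))})
    return pd.DataFrame(rows)


class TestAssembleDataset:
    def test_shape_and_exclusion(self):
        traj = toy_trajectories(20, drop_late_for=("d03",))
        X, y = md.assemble_dataset(traj, "sttc")
        assert X.shape == (19, 18) and "d03" not in X.index
        assert (y.index == X.index).all()

    def test_imputation_leaves_complete_columns(self):
        traj = toy_trajectories(12)
        traj.loc[traj["interval"] == 0, "ibi"] = np.nan
        traj.loc[(traj["interval"] == 0) & (traj["dish"] == "d00"), "ibi"] = 5.0
        before = traj[traj["interval"] == 0].set_index("dish")["mfr"]
        with pytest.warns(UserWarning, match="mean-imputing"):
            X, _ = md.assemble_dataset(traj, "sttc")
        pd.testing.assert_series_equal(X["mfr"], before.loc[X.index], check_names=False)
        assert not X["ibi"].isna().any()

    def test_insufficient_dishes_raises(self):
        with pytest.raises(ValueError, match="insufficient"):
            md.assemble_dataset(toy_trajectories(5), "sttc")

    def test_unknown_target_raises(self):
        with pytest.raises(ValueError, match="unknown target"):
            md.assemble_dataset(toy_trajectories(10), "not_a_feature")


class TestSplit:
    def test_dish_level_disjoint(self):
        dishes = [f"d{i}" for i in range(40)]
        train, test = train_test_split_dishes(dishes, 0.75, seed=3)
        assert len(train) == 30 and len(test) == 10
        assert set(train).isdisjoint(test)


class TestFitPredict:
    @pytest.mark.parametrize("model", ["mars", "svm", "rf"])
    def test_noiseless_linear_recovered(self, model):
        """All three learners fit y = 3 x_2 + 1 to test R^2 >= 0.99 at n=200."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 5))
        y = 3.0 * X[:, 2] + 1.0
        _, r2, rmse = md.fit_predict(model, X[:150], y[:150], X[150:], y[150:])
        assert r2 >= 0.99
        assert rmse >= 0.0

    def test_mean_prediction_nonpositive_r2(self, rng):
        y_true = rng.normal(size=30)
        assert md.r2_score(y_true, np.full(30, y_true[:20].mean())) <= 0.05
        # predicting the true mean exactly gives R^2 = 0
        assert md.r2_score(y_true, np.full(30, y_true.mean())) == pytest.approx(0.0)

    def test_perfect_prediction_zero_rmse(self, rng):
        X = rng.normal(size=(50, 3))
        y = X[:, 0]
        _, r2, rmse = md.fit_predict("mars", X[:40], y[:40], X[40:], y[40:])
        assert rmse == pytest.approx(0.0, abs=1e-8) and r2 == pytest.approx(1.0)

    def test_constant_test_target_flagged(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.ones(30)
        _, r2, _ = md.fit_predict("rf", X[:20], y[:20], X[20:], y[20:])
        assert math.isnan(r2)


class TestRECCurve:
    def test_perfect_predictor_steps_at_zero(self):
        curve = md.rec_curve(np.zeros(10), target_sd=1.0)
        assert (curve["accuracy"] == 1.0).all()

    def test_direct_count(self):
        curve = md.rec_curve(np.array([0.5, 1.5]), target_sd=1.0, n_points=4)
        # tolerance grid [0, 0.5, 1.0, 1.5]
        np.testing.assert_allclose(curve["accuracy"], [0.0, 0.5, 0.5, 1.0])

    def test_monotone_and_reaches_one(self, rng):
        curve = md.rec_curve(np.abs(rng.normal(size=50)), target_sd=2.0)
        assert (np.diff(curve["accuracy"]) >= 0).all()
        assert curve["accuracy"].iloc[-1] == 1.0


class TestSMOTE:
    def test_output_size(self, rng):
        rows = rng.normal(size=(30, 5))
        out = md.smote_augment(rows, k_neighbors=20, ratio=2, seed=0)
        assert out.shape == (90, 5)

    def test_componentwise_betweenness(self, rng):
        rows = rng.normal(size=(40, 4))
        out = md.smote_augment(rows, k_neighbors=10, ratio=2, seed=1)
        lo, hi = rows.min(axis=0), rows.max(axis=0)
        synth = out[40:]
        assert (synth >= lo - 1e-12).all() and (synth <= hi + 1e-12).all()

    def test_originals_preserved_and_deterministic(self, rng):
        rows = rng.normal(size=(25, 3))
        a = md.smote_augment(rows, 20, 2, seed=5)
        b = md.smote_augment(rows, 20, 2, seed=5)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(a[:25], rows)

    def test_small_n_shrinks_k(self, rng):
        rows = rng.normal(size=(10, 3))
        with pytest.warns(UserWarning, match="shrinking k"):
            out = md.smote_augment(rows, k_neighbors=20, ratio=1, seed=0)
        assert out.shape == (20, 3)


class TestRepeatedCV:
    def test_no_synthetic_rows_in_evaluation_folds(self, rng):
        """Every evaluation index refers to an original row."""
        X = rng.normal(size=(32, 6))
        y = X[:, 0] + rng.normal(0, 0.1, 32)
        cfg = md.PredictConfig(cv_iterations=2, seed=0)
        r2s, test_idx = md.repeated_cv_r2(X, y, cfg, seed=0)
        assert len(r2s) == 2 * cfg.cv_folds
        seen = np.concatenate(test_idx)
        assert seen.max() < 32 and seen.min() >= 0
        for it in range(2):
            folds = test_idx[it * 4 : (it + 1) * 4]
            assert sorted(np.concatenate(folds).tolist()) == list(range(32))

    def test_reproducible_under_seed(self, rng):
        X = rng.normal(size=(30, 4))
        y = X[:, 1]
        cfg = md.PredictConfig(cv_iterations=2, seed=0)
        a, _ = md.repeated_cv_r2(X, y, cfg, seed=9)
        b, _ = md.repeated_cv_r2(X, y, cfg, seed=9)
        assert a == b


class TestGroupImportance:
    def test_strategy_layout(self):
        strategies = importance_strategies()
        assert len(strategies) == 10
        assert len(strategies["baseline_18"]) == 18
        assert len(strategies["baseline_8"]) == 8
        assert strategies["leave_one_in_synchrony"] == ["sttc", "sttc_dbscan"]
        assert "sttc" not in strategies["leave_one_out_synchrony"]

    def test_planted_group_signal_recovered(self, rng):
        """A target built from one group ranks that group first leave-one-in."""
        n = 160
        X = pd.DataFrame(rng.normal(size=(n, 18)), columns=list(FEATURES))
        y = pd.Series(
            X["sttc"].to_numpy() + 0.5 * X["sttc_dbscan"].to_numpy(), index=X.index
        )
        cfg = md.PredictConfig(cv_iterations=3, seed=0)
        imp = md.group_importance(X, y, cfg).set_index("strategy")
        lois = imp.loc[[s for s in imp.index if s.startswith("leave_one_in")]]
        assert lois["mean_r2"].idxmax() == "leave_one_in_synchrony"
        # removing any one of the three irrelevant groups is interchangeable
        loo = imp.loc[
            ["leave_one_out_spikes", "leave_one_out_bursts",
             "leave_one_out_connectivity"], "mean_r2",
        ]
        assert loo.max() - loo.min() < 0.05
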