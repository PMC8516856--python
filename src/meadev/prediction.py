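"""Prediction of third-week feature levels from first-week activity.

For every dish with recordings in both the first (DIV 6-8) and third
(DIV 13-18) intervals, the 18 first-interval feature means are the
predictors and the third-interval mean of a chosen feature (STTC, channels
with bursts, or MFR) is the target.  Three regression learners are compared
under fixed hyperparameters:

* MARS — 5 degrees of interaction, 35 model terms (in-repo implementation);
* SVM  — RBF kernel ``k(x, y) = exp(-sigma * ||x - y||^2)`` with
  sigma = 0.125 and C = 6 (sklearn's ``gamma`` equals this sigma);
* Random Forest — 100 trees, 8 candidate variables per split.

Models are evaluated with test R², RMSE and regression error characteristic
(REC) curves on a 75/25 dish-level split.  Feature-group importance uses the
SVM under leave-one-in / leave-one-out strategies over the four balanced
feature groups, with SMOTE augmentation of the training folds and fourfold
cross-validation repeated 10 times; synthetic rows never enter evaluation
folds.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVR

from .features import FEATURE_GROUPS, FEATURES
from .mars import MARSRegressor


@dataclasses.dataclass(frozen=True)
class PredictConfig:
    targets: tuple[str, ...] = ("sttc", "ch_bursts", "mfr")
    train_fraction: float = 0.75
    mars_degree: int = 5
    mars_max_terms: int = 35
    rf_n_trees: int = 100
    rf_candidates_per_split: int = 8
    svm_gamma: float = 0.125
    svm_c: float = 6.0
    svm_epsilon: float = 0.01
    smote_k_neighbors: int = 20
    smote_ratio: int = 2
    cv_folds: int = 4
    cv_iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        for f in dataclasses.fields(self):
            if f.name in ("targets", "train_fraction", "seed"):
                continue
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")


# ---------------------------------------------------------------------------
# dataset assembly


def assemble_dataset(
    trajectories: pd.DataFrame,
    target: str,
    predictor_interval: int = 0,
    target_interval: int = 2,
) -> tuple[pd.DataFrame, pd.Series]:
    """Predictor matrix (18 first-interval means) and target vector.

    Dishes lacking either interval are excluded; missing predictor cells are
    mean-imputed columnwise (with a warning naming the columns).
    """
    if target not in FEATURES:
        raise ValueError(f"unknown target {target!r}")
    pred = trajectories[trajectories["interval"] == predictor_interval].set_index("dish")
    tgt = trajectories[trajectories["interval"] == target_interval].set_index("dish")
    dishes = sorted(set(pred.index) & set(tgt.index[tgt[target].notna()]))
    if len(dishes) < 8:
        raise ValueError(f"insufficient data: only {len(dishes)} eligible dishes")
    X = pred.loc[dishes, list(FEATURES)].copy()
    incomplete = X.columns[X.isna().any()]
    if len(incomplete):
        warnings.warn(f"mean-imputing missing cells in columns: {list(incomplete)}")
        X = X.fillna(X.mean())
    y = tgt.loc[dishes, target]
    return X, y


def train_test_split_dishes(
    dishes: list[str], train_fraction: float = 0.75, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Seeded dish-level split; no dish appears on both sides."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dishes))
    n_train = int(round(train_fraction * len(dishes)))
    train = [dishes[i] for i in sorted(order[:n_train])]
    test = [dishes[i] for i in sorted(order[n_train:])]
    return train, test


# ---------------------------------------------------------------------------
# learners


def _make_model(name: str, cfg: PredictConfig, seed: int):
    if name == "mars":
        return MARSRegressor(max_terms=cfg.mars_max_terms, max_degree=cfg.mars_degree)
    if name == "svm":
        return SVR(kernel="rbf", gamma=cfg.svm_gamma, C=cfg.svm_c, epsilon=cfg.svm_epsilon)
    if name == "rf":
        return RandomForestRegressor(
            n_estimators=cfg.rf_n_trees,
            max_features=cfg.rf_candidates_per_split,
            random_state=seed,
        )
    raise ValueError(f"unknown model {name!r}")


class _Scaler:
    """Column z-scoring fit on training rows only."""

    def fit(self, X: np.ndarray) -> "_Scaler":
        self.mu = X.mean(axis=0)
        self.sd = X.std(axis=0, ddof=0)
        self.sd = np.where(self.sd == 0, 1.0, self.sd)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mu) / self.sd


def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """R² = 1 - SS_res/SS_tot; NaN when the test target is constant."""
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        return math.nan
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot


def fit_predict(
    model_name: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    cfg: PredictConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, float, float]:
    """Fit one learner on the training rows; return (predictions, R², RMSE).

    Predictors are z-scored with statistics of the training rows.  For the
    SVM the target is also z-scored during fitting (the RBF epsilon-tube is
    scale-sensitive) and predictions are mapped back to target units.
    """
    cfg = cfg or PredictConfig()
    xs = _Scaler().fit(np.asarray(X_train, dtype=float))
    Xtr = xs.transform(np.asarray(X_train, dtype=float))
    Xte = xs.transform(np.asarray(X_test, dtype=float))
    ytr = np.asarray(y_train, dtype=float)
    model = _make_model(model_name, cfg, seed)
    if model_name == "svm":
        mu, sd = ytr.mean(), ytr.std(ddof=0) or 1.0
        model.fit(Xtr, (ytr - mu) / sd)
        pred = model.predict(Xte) * sd + mu
    else:
        model.fit(Xtr, ytr)
        pred = model.predict(Xte)
    yte = np.asarray(y_test, dtype=float)
    rmse = float(np.sqrt(np.mean((yte - pred) ** 2)))
    return pred, r2_score(yte, pred), rmse


def rec_curve(
    abs_errors: np.ndarray, target_sd: float, n_points: int = 101
) -> pd.DataFrame:
    """Regression error characteristic curve.

    Errors are standardized by the target standard deviation; the curve gives
    the fraction of points with standardized error at most epsilon, on a grid
    from 0 to the maximum observed error.
    """
    e = np.sort(np.asarray(abs_errors, dtype=float) / target_sd)
    grid = np.linspace(0.0, max(e.max(), 1e-12), n_points)
    acc = np.searchsorted(e, grid, side="right") / e.size
    return pd.DataFrame({"tolerance": grid, "accuracy": acc})


# ---------------------------------------------------------------------------
# SMOTE for regression


def smote_augment(
    rows: np.ndarray, k_neighbors: int = 20, ratio: int = 2, seed: int = 0
) -> np.ndarray:
    """SMOTE-style interpolation of predictor+target rows.

    For each original row, ``ratio`` synthetic rows are created by picking
    one of its k nearest neighbors (Euclidean distance in the joint
    predictor+target space) and interpolating with a uniform lambda in
    [0, 1].  The originals come first in the output, so ``out[:n] == rows``.
    """
    x = np.asarray(rows, dtype=float)
    n = x.shape[0]
    if n <= k_neighbors:
        warnings.warn(f"n={n} <= k={k_neighbors}; shrinking k to {n - 1}")
        k_neighbors = n - 1
    if k_neighbors < 1:
        raise ValueError("need at least 2 rows for SMOTE")
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(x)
    _, idx = nn.kneighbors(x)  # column 0 is the row itself
    synth = []
    for i in range(n):
        for _ in range(ratio):
            j = idx[i, 1 + rng.integers(k_neighbors)]
            lam = rng.uniform()
            synth.append(x[i] + lam * (x[j] - x[i]))
    return np.vstack([x] + [np.asarray(synth)]) if synth else x


# ---------------------------------------------------------------------------
# repeated CV and feature-group importance


def repeated_cv_r2(
    X: np.ndarray,
    y: np.ndarray,
    cfg: PredictConfig | None = None,
    model_name: str = "svm",
    seed: int = 0,
    augment: bool = True,
) -> tuple[list[float], list[np.ndarray]]:
    """Out-of-fold R² over ``cv_folds`` x ``cv_iterations`` evaluations.

    SMOTE augmentation (when enabled) is applied to the training fold only,
    after the split; evaluation folds contain original rows exclusively.
    Returns the R² values and the original-row test indices of each fold.
    """
    cfg = cfg or PredictConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    r2s: list[float] = []
    test_indices: list[np.ndarray] = []
    for it in range(cfg.cv_iterations):
        kf = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=(seed + it) % (2**31))
        for fold, (tr, te) in enumerate(kf.split(X)):
            Xtr, ytr = X[tr], y[tr]
            if augment:
                joint = smote_augment(
                    np.column_stack([Xtr, ytr]),
                    cfg.smote_k_neighbors,
                    cfg.smote_ratio,
                    seed=(seed + 1000 * it + fold) % (2**31),
                )
                Xtr, ytr = joint[:, :-1], joint[:, -1]
            _, r2, _ = fit_predict(model_name, Xtr, ytr, X[te], y[te], cfg, seed=seed)
            r2s.append(r2)
            test_indices.append(te)
    return r2s, test_indices


def importance_strategies(groups: dict[str, tuple[str, ...]] | None = None) -> dict[str, list[str]]:
    """Feature subsets for the baseline and leave-one-in/out strategies."""
    groups = groups or FEATURE_GROUPS
    group8 = [f for cols in groups.values() for f in cols]
    strategies: dict[str, list[str]] = {
        "baseline_18": list(FEATURES),
        "baseline_8": group8,
    }
    for name, cols in groups.items():
        strategies[f"leave_one_out_{name}"] = [f for f in group8 if f not in cols]
        strategies[f"leave_one_in_{name}"] = list(cols)
    return strategies


def group_importance(
    X: pd.DataFrame,
    y: pd.Series,
    cfg: PredictConfig | None = None,
    groups: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Mean out-of-fold R² ± SEM per strategy (SVM, SMOTE-augmented folds).

    Strategies: all 18 features, the balanced 8 group features, and, per
    feature group, leave-one-out (remove the group from the 8) and
    leave-one-in (use the group's 2 features alone).
    """
    cfg = cfg or PredictConfig()
    rows = []
    for name, cols in importance_strategies(groups).items():
        r2s, _ = repeated_cv_r2(
            X[cols].to_numpy(), y.to_numpy(), cfg, model_name="svm", seed=cfg.seed
        )
        r2s = np.asarray(r2s, dtype=float)
        rows.append(
            {
                "strategy": name,
                "mean_r2": float(np.nanmean(r2s)),
                "sem": float(np.nanstd(r2s, ddof=1) / math.sqrt(np.isfinite(r2s).sum())),
                "n_evaluations": int(np.isfinite(r2s).sum()),
            }
        )
    return pd.DataFrame(rows)


def prediction_report(
    trajectories: pd.DataFrame,
    target: str,
    cfg: PredictConfig | None = None,
) -> dict:
    """Train/test evaluation of all three learners for one target feature.

    Returns per-model test R², RMSE and REC curves, plus the dish split.
    """
    cfg = cfg or PredictConfig()
    X, y = assemble_dataset(trajectories, target)
    train, test = train_test_split_dishes(list(X.index), cfg.train_fraction, cfg.seed)
    out: dict = {"target": target, "train_dishes": train, "test_dishes": test, "models": {}}
    sd = float(y.loc[test].std(ddof=0)) or 1.0
    for name in ("mars", "svm", "rf"):
        pred, r2, rmse = fit_predict(
            name,
            X.loc[train].to_numpy(),
            y.loc[train].to_numpy(),
            X.loc[test].to_numpy(),
            y.loc[test].to_numpy(),
            cfg,
            seed=cfg.seed,
        )
        out["models"][name] = {
            "r2": r2,
            "rmse": rmse,
            "rec": rec_curve(np.abs(y.loc[test].to_numpy() - pred), sd),
            "predictions": pd.Series(pred, index=test),
        }
    return out
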