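"""Regressor roster, the composite selection score and model selection.

Candidate regressors are scored by a composite metric that rewards high
train and validation R², penalises total error (MAE + RMSE + MSE) and
penalises the train/validation gap:

    S = R2_train + R2_val          Err = MSE + RMSE + MAE
    d = |R2_train - R2_val|        C = (1 - d) / (1 + d)
    X = (S / Err) * C              score = X / (1 + X)

The score lives in [0, 1): it increases with S, decreases with Err and
with the overfitting gap d, with 1 reached only in the perfect-model
limit (zero error).  Selection runs a seeded grid search over the
roster, scoring each candidate by the composite of its mean k-fold CV
metrics, with scaling and any dimensionality reduction refitted inside
every training fold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import (AdaBoostRegressor, GradientBoostingRegressor,
                              RandomForestRegressor)
from sklearn.feature_selection import SelectKBest, f_regression
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR, NuSVR
from sklearn.tree import DecisionTreeRegressor

__all__ = ["MetricSet", "ModelCandidate", "SelectionResult", "w_new",
           "evaluate", "cross_validate", "pca_reduce", "grid_search",
           "make_estimator", "make_model_pipeline", "FAMILIES",
           "DEFAULT_ROSTER", "DEFAULT_GRIDS", "RF_TUNED"]

_EPS = 1e-12


@dataclass(frozen=True)
class MetricSet:
    """The six evaluation quantities for one fitted candidate."""

    r2_train: float
    r2_val: float
    mae: float
    rmse: float
    mse: float
    w_new: float

    def as_dict(self) -> dict:
        return {"r2_train": self.r2_train, "r2_val": self.r2_val,
                "mae": self.mae, "rmse": self.rmse, "mse": self.mse,
                "w_new": self.w_new}


def w_new(r2_train: float, r2_val: float, mae: float, rmse: float,
          mse: float) -> float:
    """Composite selection score; a pure function of its five inputs.

    Returns 0 when the accuracy-concordance product is non-positive
    (such models are never worth selecting) and 1 in the perfect-model
    limit of vanishing error with positive skill.
    """
    for name, val in (("r2_train", r2_train), ("r2_val", r2_val),
                      ("mae", mae), ("rmse", rmse), ("mse", mse)):
        if not np.isfinite(val):
            raise ValueError(f"{name} must be finite, got {val!r}")
    s = r2_train + r2_val
    err = mse + rmse + mae
    d = abs(r2_train - r2_val)
    c = (1.0 - d) / (1.0 + d)
    if err < _EPS:
        if s * c > 0:
            return 1.0
        raise ValueError("composite score undefined: zero error with "
                         "non-positive accuracy-concordance product")
    x = (s / err) * c
    if x <= 0:
        return 0.0
    return x / (1.0 + x)


def evaluate(model, train, val) -> MetricSet:
    """Six metrics for a fitted (or fittable) regressor.

    ``train`` and ``val`` are (X, y) pairs.  R2_train comes from the
    training predictions; MAE/MSE (and RMSE = sqrt(MSE)) are computed on
    the validation partition, so the error terms of the composite score
    measure generalization.  R² is 1 - SS_res/SS_tot and may be negative.
    """
    X_tr, y_tr = train
    X_val, y_val = val
    if len(y_tr) == 0 or len(y_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    if np.var(np.asarray(y_val, dtype=float)) == 0:
        raise ValueError("validation target has zero variance; R2 undefined")
    if not hasattr(model, "predict"):
        raise TypeError("model must expose a predict method")
    try:
        pred_tr = model.predict(X_tr)
    except Exception:
        model.fit(X_tr, y_tr)
        pred_tr = model.predict(X_tr)
    pred_val = model.predict(X_val)
    r2_tr = r2_score(y_tr, pred_tr)
    r2_val = r2_score(y_val, pred_val)
    mae = mean_absolute_error(y_val, pred_val)
    mse = mean_squared_error(y_val, pred_val)
    rmse = float(np.sqrt(mse))
    return MetricSet(float(r2_tr), float(r2_val), float(mae), rmse,
                     float(mse), w_new(r2_tr, r2_val, mae, rmse, mse))


# ---------------------------------------------------------------------------
# roster


#: hyperparameters selected for the forest by grid search in the screening
#: analysis: a compact forest with conservative leaf sizes.
RF_TUNED = {"n_estimators": 100, "max_depth": 10,
            "min_samples_split": 5, "min_samples_leaf": 5}

FAMILIES = {
    "knn": lambda seed, **p: KNeighborsRegressor(**p),
    "elastic_net": lambda seed, **p: ElasticNet(random_state=seed, **p),
    "linear": lambda seed, **p: LinearRegression(**p),
    "svr": lambda seed, **p: SVR(**p),
    "nu_svr": lambda seed, **p: NuSVR(**p),
    "decision_tree": lambda seed, **p: DecisionTreeRegressor(random_state=seed, **p),
    "gradient_boosting": lambda seed, **p: GradientBoostingRegressor(random_state=seed, **p),
    "random_forest": lambda seed, **p: RandomForestRegressor(
        random_state=seed, **{**RF_TUNED, **p}),
    "ada_boost": lambda seed, **p: AdaBoostRegressor(random_state=seed, **p),
}


def _xgboost_factory(seed, **p):
    from xgboost import XGBRegressor  # optional roster member

    defaults = {"n_estimators": 100, "max_depth": 6, "verbosity": 0,
                "n_jobs": 1}
    return XGBRegressor(random_state=seed, **{**defaults, **p})


FAMILIES["xgboost"] = _xgboost_factory

#: the nine-family default roster; xgboost stays available as an extra.
DEFAULT_ROSTER = ("knn", "elastic_net", "linear", "svr", "nu_svr",
                  "decision_tree", "gradient_boosting", "random_forest",
                  "ada_boost")

#: compact default grids (single point per family unless a hyperparameter
#: materially changes behaviour on tables of a few hundred rows).
DEFAULT_GRIDS = {
    "knn": {"n_neighbors": [5]},
    "elastic_net": {"alpha": [0.1]},
    "linear": {},
    "svr": {"C": [1.0]},
    "nu_svr": {"C": [1.0]},
    "decision_tree": {"max_depth": [10]},
    "gradient_boosting": {"n_estimators": [100]},
    "random_forest": {},
    "ada_boost": {"n_estimators": [50]},
    "xgboost": {"n_estimators": [100]},
}


@dataclass(frozen=True)
class ModelCandidate:
    """One point of the search space: family, grid point, reduction branch.

    ``reduction`` is 'none', ('pca', k) or ('select', k).
    """

    family: str
    params: tuple = ()  # sorted (name, value) pairs
    reduction: object = "none"

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    def label(self) -> str:
        parts = [self.family]
        if self.params:
            parts.append(",".join(f"{k}={v}" for k, v in self.params))
        if self.reduction != "none":
            parts.append(f"{self.reduction[0]}{self.reduction[1]}")
        return "|".join(parts)


def make_estimator(candidate: ModelCandidate, seed: int = 0):
    if candidate.family not in FAMILIES:
        raise KeyError(f"unknown model family {candidate.family!r}")
    return FAMILIES[candidate.family](seed, **candidate.param_dict)


def make_model_pipeline(candidate: ModelCandidate, seed: int = 0) -> Pipeline:
    """Scaler -> optional reduction -> estimator; everything refit per fold."""
    steps = [("scale", StandardScaler())]
    if candidate.reduction != "none":
        kind, k = candidate.reduction
        if kind == "pca":
            steps.append(("reduce", PCA(n_components=k, random_state=seed)))
        elif kind == "select":
            steps.append(("reduce", SelectKBest(f_regression, k=k)))
        else:
            raise ValueError(f"unknown reduction branch {kind!r}")
    steps.append(("model", make_estimator(candidate, seed)))
    return Pipeline(steps)


def cross_validate(candidate: ModelCandidate, X, y, k: int = 5,
                   seed: int | None = 0) -> list[MetricSet]:
    """Seeded k-fold CV; fold sizes differ by at most one."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of observations n={n}")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    out = []
    for tr_idx, val_idx in splitter.split(X):
        pipe = make_model_pipeline(candidate, seed=seed)
        pipe.fit(X[tr_idx], y[tr_idx])
        out.append(evaluate(pipe, (X[tr_idx], y[tr_idx]),
                            (X[val_idx], y[val_idx])))
    return out


def mean_metrics(metric_sets: list[MetricSet]) -> MetricSet:
    """Elementwise mean of fold metrics, with the composite score recomputed
    from the means (one score per candidate, as reported)."""
    r2t = float(np.mean([m.r2_train for m in metric_sets]))
    r2v = float(np.mean([m.r2_val for m in metric_sets]))
    mae = float(np.mean([m.mae for m in metric_sets]))
    rmse = float(np.mean([m.rmse for m in metric_sets]))
    mse = float(np.mean([m.mse for m in metric_sets]))
    return MetricSet(r2t, r2v, mae, rmse, mse, w_new(r2t, r2v, mae, rmse, mse))


def pca_reduce(X, k: int | None = None, variance_threshold: float | None = None):
    """Principal-component reduction of a standardized matrix.

    Exactly one of ``k`` and ``variance_threshold`` is given.  Threshold
    mode keeps the smallest k whose cumulative explained-variance
    fraction reaches the threshold.  Returns (reduced matrix, explained-
    variance fractions of the kept components).
    """
    X = np.asarray(X, dtype=float)
    if (k is None) == (variance_threshold is None):
        raise ValueError("give exactly one of k and variance_threshold")
    n_cols = X.shape[1]
    if k is not None and k > n_cols:
        raise ValueError(f"k={k} exceeds the column count {n_cols}")
    full = PCA(n_components=min(X.shape)).fit(X)
    if k is None:
        cum = np.cumsum(full.explained_variance_ratio_)
        k = int(np.searchsorted(cum, variance_threshold) + 1)
        k = min(k, len(cum))
    pca = PCA(n_components=k).fit(X)
    return pca.transform(X), pca.explained_variance_ratio_.copy()


@dataclass(frozen=True)
class SelectionResult:
    best: ModelCandidate
    holdout_metrics: MetricSet  # best candidate refit on the 70/30 split
    fold_metrics: tuple  # per-fold MetricSets of the best candidate
    leaderboard: tuple  # (candidate, mean-fold MetricSet) pairs, search order


def _grid_points(grid: dict):
    if not grid:
        yield ()
        return
    names = sorted(grid)
    for combo in itertools.product(*(grid[n] for n in names)):
        yield tuple(zip(names, combo))


def grid_search(roster, grids, X, y, k: int = 5, seed: int | None = 0,
                branches=("none",), train_fraction: float = 0.7) -> SelectionResult:
    """Exhaustive search over (family, grid point, reduction branch).

    Candidates are scored by the composite metric of their mean k-fold CV
    metrics computed on the training portion of a seeded 70/30 split; the
    winner (ties break in roster order, then lexicographic grid order,
    then branch order) is refit on the training portion and reported on
    the held-out 30 %.
    """
    roster = tuple(roster)
    if not roster:
        raise ValueError("roster must be non-empty")
    for fam in roster:
        if fam not in FAMILIES:
            raise KeyError(f"unknown model family {fam!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(y))
    n_train = int(np.floor(len(y) * train_fraction + 0.5))
    tr, te = perm[:n_train], perm[n_train:]

    leaderboard = []
    best = None
    best_score = -np.inf
    best_folds = None
    errors = []
    for fam in roster:
        for point in _grid_points(grids.get(fam, {})):
            for branch in branches:
                cand = ModelCandidate(fam, point, branch)
                try:
                    folds = cross_validate(cand, X[tr], y[tr], k=k, seed=seed)
                except Exception as exc:  # noqa: BLE001 - roster members may fail
                    errors.append((cand, exc))
                    continue
                mm = mean_metrics(folds)
                leaderboard.append((cand, mm))
                if mm.w_new > best_score:  # strict >: earlier candidate wins ties
                    best, best_score, best_folds = cand, mm.w_new, folds
    if best is None:
        raise RuntimeError(f"all {len(errors)} candidates failed; "
                           f"first error: {errors[0][1]!r}")
    pipe = make_model_pipeline(best, seed=seed)
    pipe.fit(X[tr], y[tr])
    holdout = evaluate(pipe, (X[tr], y[tr]), (X[te], y[te]))
    return SelectionResult(best, holdout, tuple(best_folds), tuple(leaderboard))


def leaderboard_frame(leaderboard, by_family: bool = True) -> pd.DataFrame:
    """Leaderboard as a metric-by-family table (rows = six metrics).

    With ``by_family`` each family contributes its best-scoring candidate,
    mirroring a published one-column-per-model comparison.
    """
    chosen = {}
    for cand, mm in leaderboard:
        key = cand.family if by_family else cand.label()
        if key not in chosen or mm.w_new > chosen[key][1].w_new:
            chosen[key] = (cand, mm)
    cols = {k: v[1].as_dict() for k, v in chosen.items()}
    frame = pd.DataFrame(cols)
    return frame.reindex(["r2_train", "r2_val", "mae", "rmse", "mse", "w_new"])
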