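"""Regression model training and validation for pIC50 prediction.

Eleven algorithms are supported (tree ensembles, boosting, k-NN, a single
tree, and four linear/regularized regressors).  Hyperparameters are chosen by
exhaustive grid search scored by mean k-fold cross-validated R²; internal
validation reports the per-fold R² with a 95% Student-t confidence interval
on the mean; external validation computes R², RMSE and MAE on a held-out
split.

The statsmodels-style entry point is :class:`QSARRegression`::

    model = QSARRegression(X_train, y_train, algorithm="extra_trees", seed=1)
    res = model.fit(n_folds=10)
    res.summary()
    res.evaluate(X_test, y_test)

where ``X`` is a scaled :class:`~dpphqsar.descriptors.DescriptorMatrix` (or a
plain DataFrame) and ``y`` the pIC50 vector.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.ensemble import (
    AdaBoostRegressor,
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import BayesianRidge, ElasticNet, Lasso, Ridge
from sklearn.model_selection import ParameterGrid
from sklearn.neighbors import KNeighborsRegressor
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from .descriptors import DescriptorMatrix, FeatureMismatchError

__all__ = [
    "ALGORITHMS",
    "ModelConfig",
    "MetricsReport",
    "CVReport",
    "QSARRegression",
    "QSARResults",
    "UnsupportedModelError",
    "default_grid",
    "make_estimator",
    "split_train_test",
    "train_test_indices",
    "r_squared",
    "rmse",
    "mae",
    "kfold_indices",
    "cross_validate",
    "grid_search",
    "feature_importances",
]

_SEEDED = frozenset(
    {"extra_trees", "gradient_boosting", "xgb", "random_forest", "adaboost", "decision_tree"}
)
_TREE_ENSEMBLES = frozenset({"extra_trees", "gradient_boosting", "xgb", "random_forest", "adaboost"})

ALGORITHMS = {
    "extra_trees": ExtraTreesRegressor,
    "gradient_boosting": GradientBoostingRegressor,
    "xgb": XGBRegressor,
    "random_forest": RandomForestRegressor,
    "knn": KNeighborsRegressor,
    "adaboost": AdaBoostRegressor,
    "decision_tree": DecisionTreeRegressor,
    "ridge": Ridge,
    "elastic_net": ElasticNet,
    "bayesian_ridge": BayesianRidge,
    "lasso": Lasso,
}


class UnsupportedModelError(TypeError):
    """Operation needs a tree-ensemble model."""


def default_grid(algorithm: str) -> dict:
    """The shipped hyperparameter grid for an algorithm (small by design)."""
    grids = json.loads(resources.files("dpphqsar").joinpath("default_grids.json").read_text())
    if algorithm not in grids:
        raise ValueError(f"unknown algorithm: {algorithm!r}")
    return grids[algorithm]


def make_estimator(algorithm: str, params: Optional[dict] = None, seed: int = 1):
    """Instantiate a fresh, unfitted scikit-learn/xgboost estimator."""
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm: {algorithm!r} (choose from {sorted(ALGORITHMS)})")
    kwargs = dict(params or {})
    if algorithm in _SEEDED:
        kwargs.setdefault("random_state", seed)
    if algorithm == "xgb":
        kwargs.setdefault("n_jobs", 1)
        kwargs.setdefault("verbosity", 0)
    if algorithm in ("extra_trees", "random_forest"):
        kwargs.setdefault("n_jobs", 1)
    return ALGORITHMS[algorithm](**kwargs)


@dataclass
class ModelConfig:
    algorithm: str
    hyperparameter_grid: Optional[dict] = None  # None -> shipped default grid
    seed: int = 1

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm: {self.algorithm!r}")
        if self.hyperparameter_grid is None:
            self.hyperparameter_grid = default_grid(self.algorithm)


# --------------------------------------------------------------------------
# data splitting

def train_test_indices(n: int, train_fraction: float = 0.8, seed: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Seeded shuffle split; the test set gets ceil((1−fraction)·n) samples."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if n < 1:
        raise ValueError("empty dataset")
    n_test = int(np.ceil((1.0 - train_fraction) * n))
    n_train = n - n_test
    if n_train == 0 or n_test == 0:
        raise ValueError(f"split of n={n} at fraction {train_fraction} leaves an empty partition")
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _to_frame(X) -> pd.DataFrame:
    if isinstance(X, DescriptorMatrix):
        return X.frame
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


def split_train_test(X, y, train_fraction: float = 0.8, seed: int = 1):
    """Split aligned X/y into (X_train, X_test, y_train, y_test)."""
    frame = _to_frame(X)
    y = np.asarray(y, dtype=float)
    if len(frame) != y.size:
        raise ValueError("X and y lengths differ")
    tr, te = train_test_indices(y.size, train_fraction, seed)
    return frame.iloc[tr], frame.iloc[te], y[tr], y[te]


# --------------------------------------------------------------------------
# metrics (external validation)

def _check_pair(y, yhat, min_len=1):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat lengths differ")
    if y.size < min_len:
        raise ValueError(f"need at least {min_len} samples")
    return y, yhat


def r_squared(y, yhat) -> float:
    """R² = 1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ)².  Negative for worse-than-mean predictors."""
    y, yhat = _check_pair(y, yhat, min_len=2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R² undefined: zero variance in y")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def rmse(y, yhat) -> float:
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(y, yhat) -> float:
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


@dataclass
class MetricsReport:
    r2: float
    rmse: float
    mae: float
    n: int

    @classmethod
    def from_predictions(cls, y, yhat) -> "MetricsReport":
        y = np.asarray(y, dtype=float)
        return cls(r2=r_squared(y, yhat), rmse=rmse(y, yhat), mae=mae(y, yhat), n=y.size)


# --------------------------------------------------------------------------
# cross-validation

def kfold_indices(n: int, n_folds: int = 10, seed: int = 1) -> list[np.ndarray]:
    """Seeded shuffle, then contiguous chunks; fold sizes differ by ≤ 1."""
    if n_folds < 2:
        raise ValueError("need at least two folds")
    if n < n_folds:
        raise ValueError("fewer samples than folds")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]


@dataclass
class CVReport:
    fold_r2: list[float]
    mean_r2: float
    median_r2: float
    ci_halfwidth: float  # 95%, Student t with len(fold_r2)-1 df

    @classmethod
    def from_fold_scores(cls, fold_r2: Sequence[float]) -> "CVReport":
        scores = np.asarray(fold_r2, dtype=float)
        k = scores.size
        if k < 2:
            raise ValueError("need at least two fold scores")
        sd = scores.std(ddof=1)
        half = float(_stats.t.ppf(0.975, k - 1) * sd / np.sqrt(k))
        return cls(
            fold_r2=[float(s) for s in scores],
            mean_r2=float(scores.mean()),
            median_r2=float(np.median(scores)),
            ci_halfwidth=half,
        )


def cross_validate(model, X, y, n_folds: int = 10, seed: int = 1) -> CVReport:
    """k-fold cross-validation of an estimator (or ModelConfig's best point).

    ``model`` may be an unfitted sklearn-style estimator (cloned per fold via
    ``get_params``/re-construction) or a :class:`ModelConfig`, in which case
    the first grid point is used.  Each fold's R² is computed on the held-out
    chunk from a model fitted on the remaining folds.
    """
    import sklearn.base

    frame = _to_frame(X)
    y = np.asarray(y, dtype=float)
    folds = kfold_indices(y.size, n_folds, seed)
    if isinstance(model, ModelConfig):
        first = next(iter(ParameterGrid(model.hyperparameter_grid))) if model.hyperparameter_grid else {}
        estimator = make_estimator(model.algorithm, first, model.seed)
    else:
        estimator = model
    scores = []
    for i, held_out in enumerate(folds):
        y_val = y[held_out]
        if np.ptp(y_val) == 0:
            raise ValueError(f"fold {i} has zero target variance; R² undefined")
        train_idx = np.setdiff1d(np.arange(y.size), held_out)
        est = sklearn.base.clone(estimator)
        est.fit(frame.iloc[train_idx].to_numpy(), y[train_idx])
        scores.append(r_squared(y_val, est.predict(frame.iloc[held_out].to_numpy())))
    return CVReport.from_fold_scores(scores)


# --------------------------------------------------------------------------
# grid search

def grid_search(config: ModelConfig, X, y, n_folds: int = 10):
    """Exhaustive grid search scored by mean k-fold CV R².

    Every grid point is evaluated; ties break toward the earlier grid point.
    A grid point that fails to fit is logged and scored −inf.  Returns
    ``(best_estimator_refit_on_all_data, best_params, best_score)``.
    """
    import sklearn.base

    frame = _to_frame(X)
    y = np.asarray(y, dtype=float)
    grid = list(ParameterGrid(config.hyperparameter_grid)) if config.hyperparameter_grid else [{}]
    folds = kfold_indices(y.size, n_folds, config.seed)
    all_idx = np.arange(y.size)

    best_score, best_params = -np.inf, None
    for params in grid:
        proto = make_estimator(config.algorithm, params, config.seed)
        fold_scores = []
        try:
            for held_out in folds:
                est = sklearn.base.clone(proto)
                train_idx = np.setdiff1d(all_idx, held_out)
                est.fit(frame.iloc[train_idx].to_numpy(), y[train_idx])
                fold_scores.append(r_squared(y[held_out], est.predict(frame.iloc[held_out].to_numpy())))
            score = float(np.mean(fold_scores))
        except Exception as exc:  # failed grid point scores -inf
            warnings.warn(f"grid point {params} failed: {exc}")
            score = -np.inf
        if score > best_score:
            best_score, best_params = score, params

    if best_params is None:
        raise RuntimeError("every grid point failed to fit")
    best = make_estimator(config.algorithm, best_params, config.seed)
    best.fit(frame.to_numpy(), y)
    return best, best_params, best_score


def feature_importances(results_or_estimator, feature_names: Optional[Sequence[str]] = None):
    """Impurity-based importances of a tree ensemble, normalized, descending."""
    if isinstance(results_or_estimator, QSARResults):
        if results_or_estimator.algorithm not in _TREE_ENSEMBLES | {"decision_tree"}:
            raise UnsupportedModelError(
                f"feature importances need a tree model, not {results_or_estimator.algorithm!r}"
            )
        est = results_or_estimator.estimator
        feature_names = results_or_estimator.feature_names
    else:
        est = results_or_estimator
    imp = getattr(est, "feature_importances_", None)
    if imp is None:
        raise UnsupportedModelError(f"{type(est).__name__} exposes no feature importances")
    imp = np.asarray(imp, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(imp.size)]
    pairs = sorted(zip(feature_names, imp), key=lambda t: (-t[1], t[0]))
    return [(n, float(v)) for n, v in pairs]


# --------------------------------------------------------------------------
# Model / Results objects

def _fingerprint(ids) -> str:
    payload = "\n".join(str(i) for i in ids).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


class QSARRegression:
    """A single-algorithm QSAR regression model on a fixed training set.

    Parameters
    ----------
    X : DescriptorMatrix or DataFrame
        Scaled descriptor matrix of the training compounds.
    y : array-like
        pIC50 vector aligned with the rows of ``X``.
    algorithm : str
        One of :data:`ALGORITHMS`.
    grid : dict, optional
        Hyperparameter grid; defaults to the shipped grid for the algorithm.
    seed : int
        Controls fold assignment and any stochastic estimator.
    """

    def __init__(self, X, y, algorithm: str = "extra_trees", grid: Optional[dict] = None, seed: int = 1):
        self.X = _to_frame(X)
        self.y = np.asarray(y, dtype=float)
        if len(self.X) != self.y.size:
            raise ValueError("X and y lengths differ")
        self.config = ModelConfig(algorithm=algorithm, hyperparameter_grid=grid, seed=seed)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target: str = "pic50", **kwargs) -> "QSARRegression":
        y = df[target].to_numpy(dtype=float)
        X = df.drop(columns=[target])
        return cls(X, y, **kwargs)

    def fit(self, n_folds: int = 10) -> "QSARResults":
        """Grid-search hyperparameters, cross-validate the winner, refit on all data."""
        estimator, best_params, _ = grid_search(self.config, self.X, self.y, n_folds)
        cv = cross_validate(
            make_estimator(self.config.algorithm, best_params, self.config.seed),
            self.X,
            self.y,
            n_folds,
            self.config.seed,
        )
        return QSARResults(
            algorithm=self.config.algorithm,
            best_params=best_params,
            seed=self.config.seed,
            estimator=estimator,
            feature_names=list(self.X.columns),
            training_fingerprint=_fingerprint(self.X.index),
            cv=cv,
            train_metrics=MetricsReport.from_predictions(self.y, estimator.predict(self.X.to_numpy())),
        )


@dataclass
class QSARResults:
    """Fitted state, cross-validation report and diagnostics of one model."""

    algorithm: str
    best_params: dict
    seed: int
    estimator: object
    feature_names: list[str]
    training_fingerprint: str
    cv: CVReport
    train_metrics: MetricsReport
    test_metrics: Optional[MetricsReport] = field(default=None)

    def _matrix(self, X) -> np.ndarray:
        frame = _to_frame(X)
        if list(frame.columns) != self.feature_names:
            if set(frame.columns) >= set(self.feature_names):
                frame = frame[self.feature_names]
            else:
                raise FeatureMismatchError("prediction matrix lacks the model's features")
        return frame.to_numpy(dtype=float)

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.estimator.predict(self._matrix(X)), dtype=float)

    def evaluate(self, X, y) -> MetricsReport:
        """External validation on held-out data; stored as ``test_metrics``."""
        report = MetricsReport.from_predictions(y, self.predict(X))
        self.test_metrics = report
        return report

    def feature_importances(self) -> list[tuple[str, float]]:
        return feature_importances(self)

    def summary(self) -> str:
        lines = [
            f"QSAR regression: {self.algorithm}",
            "=" * 44,
            f"features:            {len(self.feature_names)}",
            f"training compounds:  {self.train_metrics.n}",
            f"training fingerprint {self.training_fingerprint}",
            f"hyperparameters:     {self.best_params}",
            f"seed:                {self.seed}",
            "",
            f"10-fold CV R² mean:  {self.cv.mean_r2:.3f} ± {self.cv.ci_halfwidth:.3f} (95% CI)",
            f"10-fold CV R² median:{self.cv.median_r2:.3f}",
        ]
        if self.test_metrics is not None:
            t = self.test_metrics
            lines += [
                "",
                f"test R²:   {t.r2:.3f}",
                f"test RMSE: {t.rmse:.3f}",
                f"test MAE:  {t.mae:.3f}",
                f"test n:    {t.n}",
            ]
        return "\n".join(lines)
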