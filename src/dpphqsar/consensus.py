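"""Consensus (integrated) model with per-compound uncertainty and AD screening.

The integrated predictor averages three trained regressors (extra trees,
gradient boosting and XGBoost by default).  Per compound, the uncertainty
halfwidth is three times the sample standard deviation of the three member
predictions, so a reported value reads pIC50 = mean ± 3·sd.

Two applicability-domain definitions are implemented on the scaled training
descriptors:

* bounding box — a compound is in-domain iff every descriptor lies within the
  training [min, max] range (inclusive);
* centroid — in-domain iff its Euclidean distance to the training centroid is
  at most a chosen quantile (default: the maximum) of the training points'
  own distances.

Metrics can be recomputed on the in-domain subset only, excluding compounds
whose predictions fall outside the model's chemical space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .descriptors import FeatureMismatchError
from .modeling import MetricsReport, QSARRegression, QSARResults, _to_frame

__all__ = [
    "ADModel",
    "ConsensusModel",
    "ConsensusQSAR",
    "ConsensusResults",
    "fit_bounding_box",
    "in_domain_bb",
    "fit_centroid",
    "in_domain_centroid",
    "consensus_predict",
    "evaluate_within_ad",
    "pic50_to_mass_conc",
]

DEFAULT_MEMBERS = ("extra_trees", "gradient_boosting", "xgb")


# --------------------------------------------------------------------------
# applicability domain

@dataclass
class ADModel:
    method: str  # "bounding_box" | "centroid"
    feature_names: list[str]
    lo: Optional[np.ndarray] = None  # bounding box minima
    hi: Optional[np.ndarray] = None  # bounding box maxima
    centroid: Optional[np.ndarray] = None
    threshold: Optional[float] = None


def _ad_matrix(ad: ADModel, X) -> np.ndarray:
    frame = _to_frame(X)
    if list(frame.columns) != ad.feature_names:
        if set(frame.columns) >= set(ad.feature_names):
            frame = frame[ad.feature_names]
        else:
            raise FeatureMismatchError("AD model features missing from input")
    return frame.to_numpy(dtype=float)


def fit_bounding_box(train_X) -> ADModel:
    """Per-descriptor [min, max] box over the training set."""
    frame = _to_frame(train_X)
    if frame.empty:
        raise ValueError("cannot fit an applicability domain on an empty matrix")
    values = frame.to_numpy(dtype=float)
    return ADModel(
        method="bounding_box",
        feature_names=list(frame.columns),
        lo=values.min(axis=0),
        hi=values.max(axis=0),
    )


def in_domain_bb(ad: ADModel, X) -> np.ndarray:
    """Boolean vector: inside the box (inclusive) on every descriptor."""
    values = _ad_matrix(ad, X)
    return np.logical_and(values >= ad.lo, values <= ad.hi).all(axis=1)


def fit_centroid(train_X, quantile: float = 1.0) -> ADModel:
    """Centroid of the training set with a distance threshold.

    The threshold is the given quantile of training-point Euclidean distances
    to the centroid; at the default 1.0 every training point is in-domain.
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    frame = _to_frame(train_X)
    if frame.empty:
        raise ValueError("cannot fit an applicability domain on an empty matrix")
    values = frame.to_numpy(dtype=float)
    centroid = values.mean(axis=0)
    dists = np.linalg.norm(values - centroid, axis=1)
    return ADModel(
        method="centroid",
        feature_names=list(frame.columns),
        centroid=centroid,
        threshold=float(np.quantile(dists, quantile)),
    )


def in_domain_centroid(ad: ADModel, X) -> np.ndarray:
    values = _ad_matrix(ad, X)
    return np.linalg.norm(values - ad.centroid, axis=1) <= ad.threshold


# --------------------------------------------------------------------------
# consensus prediction

@dataclass
class ConsensusModel:
    """Exactly three trained member models sharing one feature set."""

    members: Sequence[QSARResults]

    def __post_init__(self):
        if len(self.members) != 3:
            raise ValueError("the integrated model takes exactly three members")
        names = {tuple(m.feature_names) for m in self.members}
        if len(names) != 1:
            raise FeatureMismatchError("members were trained on different feature sets")
        prints = {m.training_fingerprint for m in self.members}
        if len(prints) != 1:
            raise ValueError("members were trained on different training sets")

    @property
    def feature_names(self) -> list[str]:
        return list(self.members[0].feature_names)


def consensus_predict(
    cm: ConsensusModel,
    X,
    ad_models: Sequence[ADModel] = (),
) -> pd.DataFrame:
    """Predict with the integrated model.

    Returns one row per compound: the member predictions, their unweighted
    mean, the uncertainty halfwidth (3 × sample sd over the three members)
    and one in-domain flag per supplied AD model.
    """
    frame = _to_frame(X)
    preds = np.column_stack([m.predict(frame) for m in cm.members])
    out = pd.DataFrame(index=frame.index)
    for m, col in zip(cm.members, preds.T):
        out[f"pred_{m.algorithm}"] = col
    out["pic50_mean"] = preds.mean(axis=1)
    out["uncertainty_halfwidth"] = 3.0 * preds.std(axis=1, ddof=1)
    for ad in ad_models:
        flag = in_domain_bb(ad, frame) if ad.method == "bounding_box" else in_domain_centroid(ad, frame)
        out[f"in_ad_{'bb' if ad.method == 'bounding_box' else 'centroid'}"] = flag
    return out


def evaluate_within_ad(predictions: pd.DataFrame, y, ad_flag: str) -> tuple[MetricsReport, int]:
    """Metrics on the in-domain subset only; returns (metrics, n excluded)."""
    y = np.asarray(y, dtype=float)
    if len(predictions) != y.size:
        raise ValueError("predictions and y lengths differ")
    mask = predictions[ad_flag].to_numpy(dtype=bool)
    excluded = int((~mask).sum())
    if not mask.any():
        raise ValueError("no compound is inside the applicability domain")
    report = MetricsReport.from_predictions(y[mask], predictions.loc[mask, "pic50_mean"].to_numpy())
    return report, excluded


def pic50_to_mass_conc(pic50: float, mol_weight: float) -> float:
    """Convert a pIC50 back to a mass concentration in mg/L (≡ µg/mL)."""
    if not (math.isfinite(pic50) and math.isfinite(mol_weight)):
        raise ValueError("pic50 and mol_weight must be finite")
    if not mol_weight > 0:
        raise ValueError("mol_weight must be positive")
    return 10.0 ** (-pic50) * mol_weight * 1000.0


# --------------------------------------------------------------------------
# Model / Results objects

class ConsensusQSAR:
    """The integrated model: three tree-ensemble regressors fitted together.

    Builds three :class:`~dpphqsar.modeling.QSARRegression` models on the same
    training matrix, fits both applicability domains on that matrix, and
    returns a :class:`ConsensusResults` for prediction and screening.
    """

    def __init__(
        self,
        X,
        y,
        algorithms: Sequence[str] = DEFAULT_MEMBERS,
        grids: Optional[dict] = None,
        seed: int = 1,
        centroid_quantile: float = 1.0,
    ):
        if len(algorithms) != 3:
            raise ValueError("the integrated model takes exactly three algorithms")
        self.X = _to_frame(X)
        self.y = np.asarray(y, dtype=float)
        self.algorithms = tuple(algorithms)
        self.grids = grids or {}
        self.seed = seed
        self.centroid_quantile = centroid_quantile

    def fit(self, n_folds: int = 10) -> "ConsensusResults":
        members = [
            QSARRegression(self.X, self.y, algorithm=a, grid=self.grids.get(a), seed=self.seed).fit(n_folds)
            for a in self.algorithms
        ]
        return ConsensusResults(
            model=ConsensusModel(members=members),
            ad_bounding_box=fit_bounding_box(self.X),
            ad_centroid=fit_centroid(self.X, self.centroid_quantile),
        )


@dataclass
class ConsensusResults:
    model: ConsensusModel
    ad_bounding_box: ADModel
    ad_centroid: ADModel
    test_metrics: Optional[MetricsReport] = field(default=None)

    @property
    def members(self) -> Sequence[QSARResults]:
        return self.model.members

    def predict(self, X, with_ad: bool = True) -> pd.DataFrame:
        ads = (self.ad_bounding_box, self.ad_centroid) if with_ad else ()
        return consensus_predict(self.model, X, ads)

    def evaluate(self, X, y, within: Optional[str] = None) -> tuple[MetricsReport, int]:
        """External validation; ``within`` restricts to an AD ('bounding_box'/'centroid')."""
        preds = self.predict(X)
        if within is None:
            report = MetricsReport.from_predictions(y, preds["pic50_mean"].to_numpy())
            self.test_metrics = report
            return report, 0
        flag = {"bounding_box": "in_ad_bb", "centroid": "in_ad_centroid"}[within]
        return evaluate_within_ad(preds, y, flag)

    def feature_importances(self) -> list[tuple[str, float]]:
        """Mean of the members' normalized impurity importances, descending.

        Averaging over the three tree ensembles damps the dilution that
        impurity importance suffers among collinear descriptors in any single
        model.
        """
        names = self.model.feature_names
        stacked = np.zeros(len(names))
        for m in self.members:
            imp = dict(m.feature_importances())
            stacked += np.array([imp[n] for n in names])
        stacked /= len(self.members)
        pairs = sorted(zip(names, stacked), key=lambda t: (-t[1], t[0]))
        return [(n, float(v)) for n, v in pairs]

    def summary(self) -> str:
        lines = ["Integrated (consensus) QSAR model", "=" * 44]
        for m in self.members:
            lines.append(
                f"{m.algorithm:<18} CV R² {m.cv.mean_r2:.3f} ± {m.cv.ci_halfwidth:.3f}"
                f"  (median {m.cv.median_r2:.3f})"
            )
        lines.append(f"uncertainty: ±3·sd over member predictions")
        lines.append(
            f"AD: bounding box over {len(self.ad_bounding_box.feature_names)} descriptors; "
            f"centroid threshold {self.ad_centroid.threshold:.3f}"
        )
        if self.test_metrics is not None:
            t = self.test_metrics
            lines.append(f"test R² {t.r2:.3f}  RMSE {t.rmse:.3f}  MAE {t.mae:.3f}  (n={t.n})")
        return "\n".join(lines)
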