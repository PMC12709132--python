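"""Regression evaluation metrics, feature selection and the baseline sweep.

Metrics: RMSE, MAE, R^2, Pearson correlation (PCC), and the acceptance
interval ratio (AIR) — the fraction of predictions within a fixed absolute
tolerance (default +/-10 percent-inhibition points, boundary inclusive) of
the observations.  Baselines (ridge, lasso, random forest, gradient
boosting) are thin scikit-learn constructions consumed through a plain
fit/predict contract; they are comparison plumbing, not contributions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import PairDataset
from .errors import ValidationError

DEFAULT_AIR_TOLERANCE = 10.0
DEFAULT_FEATURE_SIZES = (2000, 4000, 6000, 8000, 10000)


def _check_pair(obs, pred) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValidationError(f"length mismatch: obs {obs.shape} vs pred {pred.shape}")
    if obs.size == 0:
        raise ValidationError("empty input")
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(pred))):
        raise ValidationError("non-finite values in obs/pred")
    return obs, pred


def rmse(obs, pred) -> float:
    """Root mean squared error."""
    obs, pred = _check_pair(obs, pred)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def mae(obs, pred) -> float:
    """Mean absolute error."""
    obs, pred = _check_pair(obs, pred)
    return float(np.mean(np.abs(obs - pred)))


def r2(obs, pred) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (can be negative)."""
    obs, pred = _check_pair(obs, pred)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    ss_res = float(np.sum((obs - pred) ** 2))
    if ss_tot == 0:
        warnings.warn("r2: constant observations; returning nan", stacklevel=2)
        return float("nan")
    return 1.0 - ss_res / ss_tot


def pcc(obs, pred) -> float:
    """Pearson product-moment correlation; nan (with warning) for constant obs/pred."""
    obs, pred = _check_pair(obs, pred)
    if obs.size < 2:
        raise ValidationError("pcc requires n >= 2")
    if obs.std() == 0 or pred.std() == 0:
        warnings.warn("pcc: undefined for constant input; returning nan", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1])


def air(obs, pred, tolerance: float = DEFAULT_AIR_TOLERANCE) -> float:
    """Acceptance interval ratio: fraction of |pred - obs| <= tolerance.

    The tolerance is in absolute percent-inhibition points and the boundary
    is inclusive.
    """
    if not tolerance > 0:
        raise ValidationError(f"tolerance must be > 0, got {tolerance}")
    obs, pred = _check_pair(obs, pred)
    return float(np.mean(np.abs(pred - obs) <= tolerance))


@dataclass
class EvalReport:
    """Five-metric evaluation of predictions on one split."""

    rmse: float
    mae: float
    r2: float
    pcc: float
    air: float
    n: int
    tolerance: float = DEFAULT_AIR_TOLERANCE

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def __str__(self) -> str:
        return (
            f"n={self.n}  RMSE={self.rmse:.4f}  MAE={self.mae:.4f}  "
            f"R2={self.r2:.4f}  PCC={self.pcc:.4f}  AIR(±{self.tolerance:g})={self.air:.4f}"
        )


def report(obs, pred, tolerance: float = DEFAULT_AIR_TOLERANCE) -> EvalReport:
    """Compute all five metrics for one obs/pred pair."""
    obs, pred = _check_pair(obs, pred)
    return EvalReport(
        rmse=rmse(obs, pred),
        mae=mae(obs, pred),
        r2=r2(obs, pred),
        pcc=pcc(obs, pred),
        air=air(obs, pred, tolerance),
        n=int(obs.size),
        tolerance=tolerance,
    )


def evaluate(model, ds: PairDataset, split: str = "test",
             tolerance: float = DEFAULT_AIR_TOLERANCE) -> EvalReport:
    """Evaluate anything with a ``predict(X)`` method on one split of a dataset."""
    sub = ds.subset(split)
    pred = np.asarray(model.predict(sub.X), dtype=float).ravel()
    return report(sub.y, pred, tolerance)


# ---------------------------------------------------------------------------
# baselines (scikit-learn behind a fit/predict contract)


class MeanPredictor:
    """Global-mean baseline: predicts the training-target mean everywhere."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.mean_)


def make_ridge(alpha: float = 1.0, seed: int = 0):
    from sklearn.linear_model import Ridge
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    return make_pipeline(StandardScaler(), Ridge(alpha=alpha, random_state=seed))


def make_lasso(alpha: float = 0.1, seed: int = 0):
    from sklearn.linear_model import Lasso
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    return make_pipeline(StandardScaler(), Lasso(alpha=alpha, random_state=seed, max_iter=5000))


def make_random_forest(n_estimators: int = 100, seed: int = 0, max_features="sqrt"):
    from sklearn.ensemble import RandomForestRegressor

    return RandomForestRegressor(
        n_estimators=n_estimators, random_state=seed, n_jobs=1, max_features=max_features
    )


def make_gradient_boosting(seed: int = 0):
    from sklearn.ensemble import HistGradientBoostingRegressor

    return HistGradientBoostingRegressor(random_state=seed)


# ---------------------------------------------------------------------------
# feature selection


def rf_importances(X, y, n_estimators: int = 100, seed: int = 0) -> np.ndarray:
    """Random-forest impurity importances (the default feature ranker)."""
    forest = make_random_forest(n_estimators=n_estimators, seed=seed)
    forest.fit(X, y)
    return forest.feature_importances_


def select_features(
    importances: np.ndarray | Callable[[np.ndarray, np.ndarray], np.ndarray],
    X_train: np.ndarray,
    y_train: np.ndarray,
    sizes: Sequence[int] = DEFAULT_FEATURE_SIZES,
) -> dict[int, np.ndarray]:
    """Top-N feature index sets per requested size.

    ``importances`` is either a precomputed nonnegative vector or a callable
    ``(X, y) -> vector``.  For each size the indices of the N largest
    importances are returned (ties broken towards the lower index, output
    sorted ascending); sets are nested across sizes by construction.
    """
    if callable(importances):
        imp = np.asarray(importances(X_train, y_train), dtype=float)
    else:
        imp = np.asarray(importances, dtype=float)
    width = X_train.shape[1]
    if imp.shape != (width,):
        raise ValidationError(f"importances shape {imp.shape} does not match width {width}")
    if np.any(imp < 0):
        raise ValidationError("importances must be nonnegative")
    for size in sizes:
        if size > width:
            raise ValidationError(f"requested size {size} exceeds feature count {width}")
        if size < 1:
            raise ValidationError("sizes must be >= 1")
    # stable ranking: descending importance, ascending index on ties
    order = np.lexsort((np.arange(width), -imp))
    return {int(size): np.sort(order[:size]) for size in sizes}


def sweep(
    factories: Mapping[str, Callable[[], object]],
    ds: PairDataset,
    sizes: Sequence[int] = DEFAULT_FEATURE_SIZES,
    importances: np.ndarray | None = None,
    ranker_seed: int = 0,
    tolerance: float = DEFAULT_AIR_TOLERANCE,
) -> pd.DataFrame:
    """Feature-selection sweep: fit every model at every feature-set size.

    Feature sets are ranked once on the training split (random-forest
    importances unless a precomputed vector is given); each factory is
    called per size to produce a fresh fit/predict estimator, fitted on the
    (reduced) training split and scored on the test split.  A failed fit
    marks its row ``failed`` and the sweep continues.
    """
    train = ds.subset("train")
    test = ds.subset("test")
    if importances is None:
        importances = rf_importances(train.X, train.y, seed=ranker_seed)
    index_sets = select_features(importances, train.X, train.y, sizes)

    rows = []
    for name, factory in factories.items():
        for size in sizes:
            idx = index_sets[int(size)]
            try:
                model = factory()
                model.fit(train.X[:, idx], train.y)
                pred = np.asarray(model.predict(test.X[:, idx]), dtype=float).ravel()
                rows.append(
                    {
                        "model": name,
                        "size": int(size),
                        "rmse": rmse(test.y, pred),
                        "pcc": pcc(test.y, pred),
                        "status": "ok",
                    }
                )
            except Exception as exc:  # noqa: BLE001 - sweep must survive one bad fit
                warnings.warn(f"sweep: {name} at size {size} failed: {exc}", stacklevel=2)
                rows.append(
                    {"model": name, "size": int(size), "rmse": np.nan, "pcc": np.nan,
                     "status": "failed"}
                )
    return pd.DataFrame(rows)
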