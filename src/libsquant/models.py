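"""Uniform fit/predict contract over the three regressors: PLSR, SVR, GBM.

PLSR uses the in-package NIPALS engine (component count fixed or chosen by
RMSECV); SVR is an RBF support vector machine with the response standardized
internally (epsilon is scale-sensitive); GBM is gradient boosting configured
as boosting_type='gbdt', num_leaves=31, max_depth=-1, learning_rate=0.1,
n_estimators=100, with per-variable importance defined as the average
split-criterion (MSE) improvement across trees.  Each fitted model carries
the channel mask it was trained on, and refuses to predict through a
mismatched mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import joblib
import numpy as np

from .pls import PLSModel, fit_pls, rmsecv

__all__ = [
    "RegressorSpec",
    "FittedModel",
    "fit_model",
    "model_predict",
    "gbm_importance",
    "DEFAULT_SPECS",
]

MODEL_NAMES = ("plsr", "svr", "gbm")

#: GBM hyperparameter tuple used throughout.
GBM_DEFAULTS: dict[str, Any] = {
    "boosting_type": "gbdt",
    "num_leaves": 31,
    "max_depth": -1,
    "learning_rate": 0.1,
    "n_estimators": 100,
}

SVR_DEFAULTS: dict[str, Any] = {
    "kernel": "rbf",
    "C": 10.0,
    "epsilon": 0.1,
    "gamma": "scale",
}

PLSR_DEFAULTS: dict[str, Any] = {
    "n_components": "auto",   # chosen by RMSECV
    "a_max": 15,
    "folds": 5,
}


@dataclass(frozen=True)
class RegressorSpec:
    """Named regressor plus its complete hyperparameter set."""

    name: str
    params: Mapping[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; expected one of {MODEL_NAMES}")

    def resolved_params(self) -> dict[str, Any]:
        defaults = {"plsr": PLSR_DEFAULTS, "svr": SVR_DEFAULTS, "gbm": GBM_DEFAULTS}[
            self.name
        ]
        out = dict(defaults)
        unknown = set(self.params) - set(defaults) - {"min_child_samples"}
        if unknown:
            raise ValueError(f"unknown {self.name} hyperparameters: {sorted(unknown)}")
        out.update(self.params)
        return out


DEFAULT_SPECS: tuple[RegressorSpec, ...] = (
    RegressorSpec("plsr"),
    RegressorSpec("svr"),
    RegressorSpec("gbm"),
)


@dataclass
class FittedModel:
    spec: RegressorSpec
    backend: Any                      # PLSModel, sklearn SVR, lightgbm, or stub
    mask: np.ndarray | None           # channel indices the model was trained on
    n_features_full: int              # p of the unmasked matrix
    extras: dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "FittedModel":
        return joblib.load(path)


class _MeanStub:
    """Zero-tree boosting degenerates to the training mean (squared loss)."""

    def __init__(self, mean: float):
        self.mean = mean

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(X).shape[0], self.mean)


def _apply_mask(X: np.ndarray, mask: np.ndarray | None, n_full: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if mask is None:
        if X.shape[1] != n_full:
            raise ValueError(f"expected {n_full} columns, got {X.shape[1]}")
        return X
    if X.shape[1] == n_full:
        return X[:, mask]
    if X.shape[1] == mask.size:
        return X
    raise ValueError(
        f"column count {X.shape[1]} matches neither the full width {n_full} "
        f"nor the mask width {mask.size}"
    )


def fit_model(
    spec: RegressorSpec,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    mask: np.ndarray | None = None,
) -> FittedModel:
    """Train one regressor on calibration rows, restricted to ``mask``.

    ``mask`` is an index array into the channels of ``X_cal`` (None = all).
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    n_full = X_cal.shape[1]
    if mask is not None:
        mask = np.asarray(mask, dtype=int)
    X = _apply_mask(X_cal, mask, n_full)
    n, p = X.shape
    params = spec.resolved_params()
    extras: dict = {}

    if spec.name == "plsr":
        a = params["n_components"]
        if a == "auto":
            a_max = min(params["a_max"], n - 1 - (n // params["folds"] + 1), p)
            a_max = max(a_max, 1)
            cv = rmsecv(X, y_cal, a_max, folds=params["folds"], seed=spec.seed)
            a = cv.best_a
            extras["rmsecv"] = cv.rmsecv
        a = min(int(a), n - 1, p)
        backend: Any = fit_pls(X, y_cal, a)
        extras["n_components"] = backend.n_components
    elif spec.name == "svr":
        from sklearn.svm import SVR

        y_mean, y_sd = float(y_cal.mean()), float(y_cal.std())
        extras["y_mean"], extras["y_sd"] = y_mean, y_sd
        if y_sd == 0:
            backend = _MeanStub(y_mean)
            extras["constant_response"] = True
        else:
            # channels are standardized for the RBF kernel (raw unit-area
            # intensities make kernel distances meaningless), the response
            # for epsilon; both transforms are undone on output
            x_mu, x_sd = X.mean(axis=0), X.std(axis=0)
            x_sd[x_sd == 0] = 1.0
            extras["x_mu"], extras["x_sd"] = x_mu, x_sd
            backend = SVR(**params)
            backend.fit((X - x_mu) / x_sd, (y_cal - y_mean) / y_sd)
    elif spec.name == "gbm":
        if params["n_estimators"] == 0:
            backend = _MeanStub(float(y_cal.mean()))
            extras["zero_estimator_stub"] = True
        else:
            from lightgbm import LGBMRegressor

            min_child = params.pop("min_child_samples", None)
            if min_child is None:
                # small-data mode: lightgbm's default leaf constraints yield
                # constant predictions on tiny calibration sets
                min_child = 20 if n >= 100 else 2
            backend = LGBMRegressor(
                **params,
                min_child_samples=min_child,
                random_state=spec.seed,
                deterministic=True,
                force_row_wise=True,
                n_jobs=1,
                verbose=-1,
            )
            backend.fit(X, y_cal)
    else:  # pragma: no cover - guarded by RegressorSpec
        raise ValueError(spec.name)

    return FittedModel(
        spec=spec, backend=backend, mask=mask, n_features_full=n_full, extras=extras
    )


def model_predict(model: FittedModel, X_new: np.ndarray) -> np.ndarray:
    """Predict concentrations (mg kg^-1) for new spectra.

    ``X_new`` may carry either the full channel width (the training mask is
    applied) or exactly the masked width.
    """
    import warnings

    X = _apply_mask(X_new, model.mask, model.n_features_full)
    with warnings.catch_warnings():
        # lightgbm's sklearn wrapper records synthetic feature names at fit
        # time; predicting from a plain array then trips a spurious warning
        warnings.filterwarnings("ignore", message=".*valid feature names.*")
        if model.spec.name == "svr" and not model.extras.get("constant_response"):
            Z = (X - model.extras["x_mu"]) / model.extras["x_sd"]
            pred = model.extras["y_mean"] + model.extras["y_sd"] * model.backend.predict(Z)
        else:
            pred = model.backend.predict(X)
    pred = np.asarray(pred, dtype=float)
    if not np.all(np.isfinite(pred)):
        raise RuntimeError("model produced non-finite predictions")
    return pred


def gbm_importance(model: FittedModel) -> np.ndarray:
    """Per-variable importance: average MSE-gain per split, normalized to 1.

    Total split gain per variable divided by the variable's split count
    (the average improvement contributed each time the variable is used),
    then normalized over active variables.  A model with no splits (e.g.
    a constant response) is reported as uniform and flagged in
    ``model.extras['importance_degenerate']``.
    """
    if model.spec.name != "gbm":
        raise ValueError(f"variable importance is defined for gbm, not {model.spec.name}")
    if isinstance(model.backend, _MeanStub):
        n = model.mask.size if model.mask is not None else model.n_features_full
        model.extras["importance_degenerate"] = True
        return np.full(n, 1.0 / n)
    booster = model.backend.booster_
    gain = booster.feature_importance(importance_type="gain").astype(float)
    splits = booster.feature_importance(importance_type="split").astype(float)
    avg_gain = gain / np.maximum(splits, 1.0)
    total = avg_gain.sum()
    if total == 0:
        model.extras["importance_degenerate"] = True
        return np.full(avg_gain.size, 1.0 / avg_gain.size)
    return avg_gain / total
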