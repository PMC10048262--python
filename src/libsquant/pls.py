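"""Partial least squares regression (PLS1) via NIPALS, with K-fold RMSECV.

A single-response NIPALS implementation written for verifiability: columns
of ``X`` and ``y`` are mean-centered (no autoscaling — spectral channels
share units), components are extracted by successive deflation, and the
regression coefficient vector ``b`` on the original variable scale is
assembled from the weight/loading structure.  For one response the NIPALS
weight step is closed-form (w proportional to X'y), so each component costs
two matrix-vector products plus a rank-one deflation.

``b`` is what the wavelength selectors rank channels by; ``rmsecv`` is the
subset-quality criterion they minimize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSModel", "CVResult", "fit_pls", "pls_predict", "rmsecv"]


@dataclass
class PLSModel:
    """Fitted PLS1 state.

    ``rotation`` (often written R = W (P'W)^-1) maps centered X directly to
    scores, and ``coef(k)`` gives the coefficient vector using the first k
    components; predictions through ``b`` and through the latent-variable
    route agree to numerical precision.
    """

    x_mean: np.ndarray            # (p,)
    y_mean: float
    weights: np.ndarray           # W, (p, A)
    x_loadings: np.ndarray        # P, (p, A)
    y_loadings: np.ndarray        # q, (A,)
    rotation: np.ndarray          # R = W (P'W)^-1, (p, A)
    n_components: int             # attained components (may be < requested)
    n_components_requested: int

    @property
    def coef_(self) -> np.ndarray:
        """Regression coefficients b on the original variable scale."""
        return self.coef(self.n_components)

    @property
    def intercept_(self) -> float:
        return self.y_mean - float(self.x_mean @ self.coef_)

    def coef(self, k: int) -> np.ndarray:
        """b using the first k components (upper-triangularity of P'W makes
        the k-component coefficients a prefix contraction of the rotation)."""
        k = min(k, self.n_components)
        return self.rotation[:, :k] @ self.y_loadings[:k]

    def predict(self, X: np.ndarray, k: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.x_mean.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} columns, model was trained on "
                f"{self.x_mean.shape[0]}"
            )
        b = self.coef_ if k is None else self.coef(k)
        return self.y_mean + (X - self.x_mean) @ b

    def predict_all_components(self, X: np.ndarray) -> np.ndarray:
        """(n, A) matrix whose column k-1 is the k-component prediction."""
        X = np.asarray(X, dtype=float)
        Z = (X - self.x_mean) @ self.rotation
        return self.y_mean + np.cumsum(Z * self.y_loadings, axis=1)

    def predict_latent(self, X: np.ndarray) -> np.ndarray:
        """Prediction through explicit score computation with deflation
        (independent route used to cross-check ``predict``)."""
        X = np.asarray(X, dtype=float)
        Xd = X - self.x_mean
        y = np.full(X.shape[0], self.y_mean)
        for a in range(self.n_components):
            t = Xd @ self.weights[:, a]
            y += self.y_loadings[a] * t
            Xd = Xd - np.outer(t, self.x_loadings[:, a])
        return y


@dataclass
class CVResult:
    """RMSECV per candidate component count; best A is the smallest argmin."""

    rmsecv: np.ndarray            # (A_max,), rmsecv[a-1] for a components
    folds: int
    fold_assignment: np.ndarray   # (n,), fold id per sample

    @property
    def best_a(self) -> int:
        return int(np.argmin(self.rmsecv)) + 1  # argmin returns first minimum

    @property
    def best_rmsecv(self) -> float:
        return float(self.rmsecv[self.best_a - 1])

    def as_dict(self) -> dict:
        """Plain-type view for JSON diagnostics."""
        return {
            "rmsecv": [float(v) for v in self.rmsecv],
            "folds": int(self.folds),
            "best_a": self.best_a,
            "best_rmsecv": self.best_rmsecv,
        }


def fit_pls(X: np.ndarray, y: np.ndarray, A: int) -> PLSModel:
    """NIPALS PLS1 fit with A components.

    Stops early (recording the attained count) once the deflated covariance
    X'y is numerically exhausted — at that point further components cannot
    change predictions.  Raises if X carries no signal at all (every column
    zero-variance after centering) or if X and y are exactly uncorrelated.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"y length {y.shape[0]} does not match n={n}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite with no missing values")
    if A < 1:
        raise ValueError("need at least one component")
    if A > min(n - 1, p):
        raise ValueError(f"A={A} exceeds min(n-1, p)={min(n - 1, p)}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean

    col_norms = np.linalg.norm(Xd, axis=0)
    if np.all(col_norms == 0):
        offending = np.flatnonzero(col_norms == 0)
        shown = ", ".join(map(str, offending[:10]))
        more = "" if offending.size <= 10 else f" (+{offending.size - 10} more)"
        raise ValueError(
            f"degenerate X: all columns have zero variance after centering "
            f"(columns {shown}{more})"
        )

    cov0 = np.linalg.norm(Xd.T @ yd)
    if cov0 == 0:
        raise ValueError("degenerate fit: X'y is exactly zero (y constant or orthogonal)")
    tol = 1e-12 * cov0

    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    attained = 0
    for a in range(A):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= tol:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 1e-30:
            break
        P[:, a] = (Xd.T @ t) / tt
        q[a] = float(yd @ t) / tt
        W[:, a] = w
        Xd -= np.outer(t, P[:, a])
        yd = yd - q[a] * t
        attained += 1

    if attained == 0:
        raise ValueError("NIPALS extracted no components (degenerate inputs)")
    W, P, q = W[:, :attained], P[:, :attained], q[:attained]
    M = P.T @ W                      # upper triangular, unit diagonal
    R = W @ np.linalg.solve(M, np.eye(attained))
    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        rotation=R,
        n_components=attained,
        n_components_requested=A,
    )


def pls_predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """y-hat = (X_new - x_mean) b + intercept."""
    return model.predict(X_new)


def rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    A_max: int,
    folds: int = 5,
    seed: int = 0,
    fold_assignment: np.ndarray | None = None,
) -> CVResult:
    """K-fold RMSECV over component counts 1..A_max.

    One fold partition (fixed by ``seed``, or supplied explicitly) is shared
    by every component count; each fold is fit once at the largest feasible
    count and out-of-fold predictions for all prefixes are pooled.  A_max is
    capped at fold-wise feasibility with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not 2 <= folds <= n:
        raise ValueError(f"folds must be between 2 and n={n}")

    if fold_assignment is None:
        fold_assignment = np.random.default_rng(seed).permutation(n) % folds
    else:
        fold_assignment = np.asarray(fold_assignment)
        if fold_assignment.shape[0] != n:
            raise ValueError("fold_assignment length must equal n")

    min_train = min(n - int(np.sum(fold_assignment == f)) for f in range(folds))
    a_cap = min(A_max, min_train - 1, p)
    if a_cap < A_max:
        warnings.warn(
            f"A_max={A_max} infeasible with these folds; capped at {a_cap}",
            stacklevel=2,
        )
    if a_cap < 1:
        raise ValueError("no feasible component count under this fold scheme")

    sse = np.zeros(a_cap)
    for f in range(folds):
        test = fold_assignment == f
        model = fit_pls(X[~test], y[~test], a_cap)
        preds = model.predict_all_components(X[test])  # (n_test, attained)
        if preds.shape[1] < a_cap:  # early stop: pad with the last prediction
            pad = np.repeat(preds[:, -1:], a_cap - preds.shape[1], axis=1)
            preds = np.hstack([preds, pad])
        sse += np.sum((preds - y[test, None]) ** 2, axis=0)
    return CVResult(
        rmsecv=np.sqrt(sse / n), folds=folds, fold_assignment=fold_assignment
    )
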