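"""Wavelength selection: CARS, random frog, and UVE.

LIBS spectra are wide (hundreds to thousands of channels) and strongly
collinear — several emission lines per element, several channels per line.
All three selectors here consume calibration spectra only and return the
channel subset they judge informative, plus per-method diagnostics:

* CARS (competitive adaptive reweighted sampling) runs a survival-of-the-
  fittest schedule: per run, a PLS model on a Monte-Carlo row subsample
  ranks surviving channels by |b|, an exponentially decreasing function
  (EDF) forces retention of the top fraction, adaptive reweighted sampling
  (weighted draws proportional to |b|) competes channels against each
  other, and the run's subset is scored by RMSECV.  The subset with the
  lowest RMSECV across runs wins.
* Random frog iterates a subset-proposal chain: candidate subsets of
  normally-perturbed size are built by adding top-ranked outside channels
  or dropping bottom-ranked inside channels, accepted if they lower RMSECV
  (or with a small probability otherwise), and each channel's selection
  probability P_j = N_j / N over the N iterations measures its importance.
* UVE (uninformative variable elimination) appends known-noise columns to
  the spectra, jackknifes PLS coefficients leave-one-out, scores each
  column by the stability c_j = mean(b_j)/sd(b_j), and discards real
  channels whose |c_j| does not beat the noise-column cutoff.

Selection never sees validation or prediction rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pls import fit_pls, rmsecv

__all__ = [
    "SelectionResult",
    "CarsConfig",
    "FrogConfig",
    "UveConfig",
    "edf_schedule",
    "cars_select",
    "random_frog_select",
    "uve_select",
]

logger = logging.getLogger("libsquant.selection")


@dataclass
class SelectionResult:
    """Selected channel indices plus per-method diagnostics."""

    method: str
    indices: np.ndarray          # unique, sorted, within [0, p)
    n_channels: int              # p of the input matrix
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and (
            self.indices.min() < 0 or self.indices.max() >= self.n_channels
        ):
            raise ValueError("selected indices out of range")
        if np.unique(self.indices).size != self.indices.size:
            raise ValueError("selected indices must be unique")
        self.indices = np.sort(self.indices)

    @property
    def n_selected(self) -> int:
        return int(self.indices.size)

    def to_json(self, path, wavelengths: np.ndarray | None = None) -> None:
        def _clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        payload = {
            "method": self.method,
            "indices": self.indices.tolist(),
            "n_channels": self.n_channels,
            "diagnostics": _clean(self.diagnostics),
        }
        if wavelengths is not None:
            payload["wavelengths_nm"] = [float(wavelengths[i]) for i in self.indices]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def scores_frame(self, wavelengths: np.ndarray) -> pd.DataFrame:
        """Flat per-channel score table (for selection-distribution plots)."""
        score_key = {
            "cars": "selection_count",
            "frog": "probabilities",
            "uve": "stability_real",
        }.get(self.method)
        scores = self.diagnostics.get(score_key)
        if scores is None:
            scores = np.isin(np.arange(self.n_channels), self.indices).astype(float)
        selected = np.zeros(self.n_channels, dtype=int)
        selected[self.indices] = 1
        return pd.DataFrame(
            {
                "wavelength_nm": np.asarray(wavelengths),
                "score": np.asarray(scores, dtype=float),
                "selected": selected,
            }
        )


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CarsConfig:
    n_runs: int = 50
    mc_fraction: float = 0.8      # Monte-Carlo row subsample per run
    folds: int = 5
    max_components: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("CARS needs at least 2 runs")
        if not 0 < self.mc_fraction <= 1:
            raise ValueError("mc_fraction must be in (0, 1]")


@dataclass(frozen=True)
class FrogConfig:
    n_iterations: int = 1000
    q0: int | None = None         # initial subset size; default p // 10
    theta: float = 0.3            # candidate-size spread (sd = theta * Q)
    eta: float = 0.1              # inferior-candidate acceptance factor
    folds: int = 5
    max_components: int = 10
    seed: int = 0
    selection_rule: str = "min_rmsecv"   # or "threshold"
    probability_threshold: float = 0.5   # used by the "threshold" rule
    candidate_ks: tuple[int, ...] | None = None  # default 5, 10, ... <= min(p, 200)

    def __post_init__(self) -> None:
        if not 0 < self.eta <= 1:
            raise ValueError("eta must be in (0, 1]")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.q0 is not None and self.q0 < 1:
            raise ValueError("q0 must be >= 1")
        if self.selection_rule not in ("min_rmsecv", "threshold"):
            raise ValueError(f"unknown selection rule {self.selection_rule!r}")


@dataclass(frozen=True)
class UveConfig:
    n_noise: int | None = None    # noise column count; default p
    noise_amplitude: float = 1e-10
    cutoff_rule: str = "quantile"  # or "max"
    cutoff_quantile: float = 0.99
    n_components: int | None = None   # None = RMSECV-optimal on the real channels
    folds: int = 5                    # folds for the component-count CV
    max_components: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_amplitude <= 0:
            raise ValueError("noise amplitude must be > 0")
        if not 0 < self.cutoff_quantile <= 1:
            raise ValueError("cutoff quantile must be in (0, 1]")
        if self.cutoff_rule not in ("quantile", "max"):
            raise ValueError(f"unknown cutoff rule {self.cutoff_rule!r}")


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _subset_rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    cols: np.ndarray,
    fold_assignment: np.ndarray,
    folds: int,
    max_components: int,
) -> float:
    """Best RMSECV over feasible component counts for one channel subset.

    One fold partition is shared across every subset scored within a
    selector run, so subsets compete on the same cross-validation."""
    n = X.shape[0]
    min_train = min(n - int(np.sum(fold_assignment == f)) for f in range(folds))
    a_max = min(max_components, min_train - 1, len(cols))
    if a_max < 1:
        return np.inf
    try:
        cv = rmsecv(
            X[:, cols], y, a_max, folds=folds, fold_assignment=fold_assignment
        )
    except ValueError:
        return np.inf
    return cv.best_rmsecv


def _rank_fit_abs_coef(
    X: np.ndarray, y: np.ndarray, cols: np.ndarray, a_rank: int
) -> np.ndarray:
    """|b| over the given columns from a PLS fit (ranking signal).

    The component count must be chosen by cross-validation upstream:
    past the CV optimum, extra components chase residual noise through
    low-variance channels whose original-scale coefficients explode,
    destroying the ranking."""
    a = min(a_rank, X.shape[0] - 1, len(cols))
    model = fit_pls(X[:, cols], y, a)
    return np.abs(model.coef_)


def _cv_components(
    X: np.ndarray, y: np.ndarray, folds: int, max_components: int, seed: int
) -> int:
    """RMSECV-optimal component count on the full calibration matrix."""
    n = X.shape[0]
    a_max = min(max_components, n - (n // folds + 1) - 1, X.shape[1])
    cv = rmsecv(X, y, max(a_max, 1), folds=folds, seed=seed)
    return cv.best_a


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------

def edf_schedule(p: int, N: int) -> np.ndarray:
    """Exponentially decreasing retention ratios r_i = a e^(-k i), i = 1..N.

    The constants a = (p/2)^(1/(N-1)) and k = ln(p/2)/(N-1) pin the schedule
    so that r_1 = 1 (all channels survive run 1) and r_N = 2/p (two channels
    survive the last run).
    """
    if p < 3:
        raise ValueError("edf_schedule needs p >= 3 (2/p >= 1 breaks monotonicity)")
    if N < 2:
        raise ValueError("edf_schedule needs N >= 2")
    a = (p / 2.0) ** (1.0 / (N - 1))
    k = np.log(p / 2.0) / (N - 1)
    i = np.arange(1, N + 1)
    return a * np.exp(-k * i)


def cars_select(
    X_cal: np.ndarray, y_cal: np.ndarray, config: CarsConfig = CarsConfig()
) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    Per run i: PLS on a Monte-Carlo subsample of calibration rows restricted
    to surviving channels ranks them by |b|; EDF retention keeps the top
    ceil(r_i p); adaptive reweighted sampling draws ceil(r_i p) channels with
    replacement with probability proportional to |b| and keeps the unique
    hits; the surviving subset is scored by K-fold RMSECV on all calibration
    rows.  The subset with the lowest RMSECV across runs is returned.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    n, p = X_cal.shape
    rng = np.random.default_rng(config.seed)
    fold_assignment = rng.permutation(n) % config.folds
    schedule = edf_schedule(p, config.n_runs)
    a_rank = _cv_components(X_cal, y_cal, config.folds, config.max_components, config.seed)

    survivors = np.arange(p)
    n_rows = max(2, int(np.ceil(config.mc_fraction * n)))
    subsets: list[np.ndarray] = []
    sizes: list[int] = []
    caps: list[int] = []
    trace: list[float] = []
    counts = np.zeros(p)

    for i in range(config.n_runs):
        rows = rng.choice(n, size=n_rows, replace=False)
        try:
            b = _rank_fit_abs_coef(X_cal[rows], y_cal[rows], survivors, a_rank)
        except ValueError:
            logger.warning("CARS run %d: degenerate ranking fit, stopping early", i + 1)
            break
        cap = int(np.ceil(schedule[i] * p))  # schedule is on the original p
        # EDF-forced retention of the top-|b| channels
        keep = np.argsort(-b, kind="stable")[: min(cap, survivors.size)]
        survivors_edf = survivors[keep]
        w = b[keep]
        # adaptive reweighted sampling: weighted draw with replacement
        drawn = rng.choice(survivors_edf, size=cap, replace=True, p=w / w.sum())
        survivors = np.unique(drawn)
        if survivors.size < 2:
            logger.warning(
                "CARS run %d: %d surviving channels, truncating schedule",
                i + 1,
                survivors.size,
            )
            break
        counts[survivors] += 1
        subsets.append(survivors.copy())
        sizes.append(int(survivors.size))
        caps.append(cap)
        trace.append(
            _subset_rmsecv(
                X_cal, y_cal, survivors, fold_assignment, config.folds, config.max_components
            )
        )

    if not trace:
        raise RuntimeError("CARS produced no scorable subset")
    trace_arr = np.asarray(trace)
    best_run = int(np.argmin(trace_arr))
    return SelectionResult(
        method="cars",
        indices=subsets[best_run],
        n_channels=p,
        diagnostics={
            "rmsecv_trace": trace_arr,
            "subset_sizes": np.asarray(sizes),
            "edf_caps": np.asarray(caps),
            "best_run": best_run,
            "best_rmsecv": float(trace_arr[best_run]),
            "selection_count": counts,
            "n_runs_completed": len(trace),
            "ranking_components": a_rank,
        },
    )


# ---------------------------------------------------------------------------
# random frog
# ---------------------------------------------------------------------------

def random_frog_select(
    X_cal: np.ndarray, y_cal: np.ndarray, config: FrogConfig = FrogConfig()
) -> SelectionResult:
    """Random frog: subset-proposal iteration with selection probabilities.

    Starting from a random subset of size Q0, each of N iterations proposes
    a candidate of size Q* ~ |round(Normal(Q, theta Q))| (at least 1) by
    adding the top-ranked outside channels or dropping the bottom-ranked
    inside channels (ranked by |b| from a PLS fit), accepts it if its RMSECV
    does not exceed the current subset's (otherwise with probability
    eta * RMSECV(current) / RMSECV(candidate)), and counts N_j, the number
    of iterations channel j spends in the retained subset.  P_j = N_j / N.
    The final subset follows the configured rule: minimum-RMSECV top-k by
    P_j (default) or a probability threshold.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    n, p = X_cal.shape
    rng = np.random.default_rng(config.seed)
    fold_assignment = rng.permutation(n) % config.folds
    score = lambda cols: _subset_rmsecv(  # noqa: E731
        X_cal, y_cal, cols, fold_assignment, config.folds, config.max_components
    )
    a_rank = _cv_components(X_cal, y_cal, config.folds, config.max_components, config.seed)

    q0 = config.q0 if config.q0 is not None else max(1, p // 10)
    q0 = min(q0, p)
    current = np.sort(rng.choice(p, size=q0, replace=False))
    current_score = score(current)

    counts = np.zeros(p)
    size_trace = np.empty(config.n_iterations, dtype=int)
    n_accepted = 0
    n_nonfinite = 0
    N = config.n_iterations
    for it in range(N):
        q = current.size
        q_star = int(abs(round(rng.normal(q, config.theta * q))))
        q_star = min(max(q_star, 1), p)
        if q_star == q:
            candidate, cand_score = current, current_score
        elif q_star < q:
            b = _rank_fit_abs_coef(X_cal, y_cal, current, a_rank)
            keep = np.argsort(-b, kind="stable")[:q_star]
            candidate = np.sort(current[keep])
            cand_score = score(candidate)
        else:
            outside = np.setdiff1d(np.arange(p), current, assume_unique=False)
            if outside.size == 0:
                candidate, cand_score = current, current_score
            else:
                n_add = min(q_star - q, outside.size)
                try:
                    b_out = _rank_fit_abs_coef(X_cal, y_cal, outside, a_rank)
                    add = outside[np.argsort(-b_out, kind="stable")[:n_add]]
                except ValueError:
                    add = rng.choice(outside, size=n_add, replace=False)
                candidate = np.sort(np.concatenate([current, add]))
                cand_score = score(candidate)

        if not np.isfinite(cand_score):
            n_nonfinite += 1
            logger.debug("random frog: non-finite RMSECV, candidate rejected")
        elif cand_score <= current_score or rng.random() < (
            config.eta * current_score / cand_score
        ):
            current, current_score = candidate, cand_score
            n_accepted += 1
        counts[current] += 1
        size_trace[it] = current.size

    probabilities = counts / N
    order = np.lexsort((np.arange(p), -probabilities))  # P_j desc, index asc

    if config.selection_rule == "threshold":
        selected = np.flatnonzero(probabilities >= config.probability_threshold)
        k_trace = {}
    else:
        ks = config.candidate_ks
        if ks is None:
            ks = tuple(range(5, min(p, 200) + 1, 5))
        ks = tuple(k for k in ks if 1 <= k <= p) or (min(5, p),)
        k_scores = {k: score(np.sort(order[:k])) for k in ks}
        best_k = min(k_scores, key=lambda k: (k_scores[k], k))
        selected = np.sort(order[:best_k])
        k_trace = {int(k): float(v) for k, v in k_scores.items()}

    return SelectionResult(
        method="frog",
        indices=selected,
        n_channels=p,
        diagnostics={
            "counts": counts,
            "probabilities": probabilities,
            "subset_size_trace": size_trace,
            "n_iterations": N,
            "n_accepted": n_accepted,
            "n_nonfinite_rejected": n_nonfinite,
            "ranking_components": a_rank,
            "k_rmsecv": k_trace,
            "final_rmsecv": float(score(selected)) if selected.size else np.inf,
        },
    )


# ---------------------------------------------------------------------------
# UVE
# ---------------------------------------------------------------------------

def uve_select(
    X_cal: np.ndarray, y_cal: np.ndarray, config: UveConfig = UveConfig()
) -> SelectionResult:
    """Uninformative variable elimination.

    Appends a block of uniform noise columns, jackknifes PLS coefficients
    leave-one-out on the augmented matrix, and scores every column by the
    stability c_j = mean(b_j) / sd(b_j) across replicates.  Real channels
    are kept when |c_j| exceeds the cutoff computed from the noise block
    (a quantile of |c| by default — the maximum is unstable with many noise
    columns).  Noise columns are never part of the selection.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    n, p = X_cal.shape
    if n < 3:
        raise ValueError("UVE needs at least 3 calibration samples for LOO")
    rng = np.random.default_rng(config.seed)
    n_noise = config.n_noise if config.n_noise is not None else p
    noise = rng.uniform(0.0, 1.0, (n, n_noise)) * config.noise_amplitude
    X_aug = np.hstack([X_cal, noise])

    if config.n_components is None:
        # past the CV-optimal depth the jackknifed coefficients are dominated
        # by noise-chasing components and the stability contrast collapses
        a = _cv_components(X_cal, y_cal, config.folds, config.max_components, config.seed)
    else:
        a = config.n_components
    a = min(a, n - 2, p + n_noise)
    B = np.empty((n, p + n_noise))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = fit_pls(X_aug[mask], y_cal[mask], a)
        B[i] = model.coef_
        mask[i] = True

    mean_b = B.mean(axis=0)
    sd_b = B.std(axis=0, ddof=1)
    zero_sd = sd_b == 0
    if np.any(zero_sd):
        logger.warning("UVE: %d columns with zero coefficient sd", int(zero_sd.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        stability = np.where(
            zero_sd, np.sign(mean_b) * np.inf, mean_b / np.where(zero_sd, 1.0, sd_b)
        )
    stability = np.where(zero_sd & (mean_b == 0), 0.0, stability)

    abs_noise = np.abs(stability[p:])
    finite_noise = abs_noise[np.isfinite(abs_noise)]
    if config.cutoff_rule == "max":
        cutoff = float(abs_noise.max()) if abs_noise.size else 0.0
    else:
        cutoff = (
            float(np.quantile(finite_noise, config.cutoff_quantile))
            if finite_noise.size
            else 0.0
        )
    selected = np.flatnonzero(np.abs(stability[:p]) > cutoff)
    return SelectionResult(
        method="uve",
        indices=selected,
        n_channels=p,
        diagnostics={
            "stability_real": stability[:p],
            "stability_noise": stability[p:],
            "cutoff": cutoff,
            "n_components": a,
            "n_noise": n_noise,
        },
    )
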