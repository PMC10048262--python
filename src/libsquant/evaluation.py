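"""Metrics, the full element x model x selector experiment grid, and
descriptive statistics of the concentration design.

Model quality is reported per subset as RC2/RMSEC (calibration), RV2/RMSEV
(validation) and RP2/RMSEP (prediction), with R^2 = 1 - SSE/SST (SST about
the mean of the reference values — not squared Pearson correlation, which
differs off the 45-degree line) and RMSE in mg kg^-1.  The experiment grid
covers every element with every regressor on the full spectrum and on each
selector's channels: 3 elements x 3 models x (full + CARS + RF + UVE) = 36
cells, all sharing one calibration/validation/prediction split.  The
validation set is purely reportorial; no model choice uses it.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import DEFAULT_SPECS, RegressorSpec, fit_model, model_predict
from .preprocessing import DEFAULT_FRACTIONS, SplitIndices, area_normalize, split_dataset
from .selection import (
    CarsConfig,
    FrogConfig,
    SelectionResult,
    UveConfig,
    cars_select,
    random_frog_select,
    uve_select,
)
from .synthetic import SpectrumSet

__all__ = [
    "Metrics",
    "ExperimentConfig",
    "EvaluationReport",
    "compute_metrics",
    "run_experiment",
    "descriptive_stats",
    "derive_seed",
]

SELECTOR_STATES = ("full", "cars", "frog", "uve")


def derive_seed(master_seed: int, *parts) -> int:
    """Stable per-stage seed below 2^31, decoupled across stages/elements."""
    token = ":".join([str(master_seed), *map(str, parts)])
    return zlib.crc32(token.encode()) % (2**31 - 1)


@dataclass(frozen=True)
class Metrics:
    """Goodness-of-fit pair for one subset: R^2 (dimensionless) and RMSE
    (mg kg^-1) over n samples."""

    r_squared: float
    rmse: float
    n: int
    degenerate: bool = False   # reference values had zero variance

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("metrics need at least 2 samples")
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, r2_definition: str = "nash"
) -> Metrics:
    """RMSE = sqrt(mean squared error); R^2 = 1 - SSE/SST (default).

    ``r2_definition="pearson"`` switches to the squared Pearson correlation,
    which differs from 1 - SSE/SST whenever predictions sit off the
    45-degree line.  Zero SST (constant reference) leaves R^2 undefined:
    reported as NaN with the ``degenerate`` flag set.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size < 2:
        raise ValueError("metrics need at least 2 samples")
    if not (np.all(np.isfinite(y_true)) and np.all(np.isfinite(y_pred))):
        raise ValueError("metrics inputs must be finite")
    if r2_definition not in ("nash", "pearson"):
        raise ValueError(f"unknown r2 definition {r2_definition!r}")
    sse = float(np.sum((y_true - y_pred) ** 2))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    rmse = float(np.sqrt(sse / y_true.size))
    if sst == 0:
        return Metrics(r_squared=float("nan"), rmse=rmse, n=y_true.size, degenerate=True)
    if r2_definition == "pearson":
        if np.std(y_pred) == 0:
            return Metrics(
                r_squared=float("nan"), rmse=rmse, n=y_true.size, degenerate=True
            )
        r2 = float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)
    else:
        r2 = 1.0 - sse / sst
    return Metrics(r_squared=r2, rmse=rmse, n=y_true.size)


# ---------------------------------------------------------------------------
# experiment grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    elements: tuple[str, ...] = ("Cd", "Cu", "Pb")
    model_specs: tuple[RegressorSpec, ...] = DEFAULT_SPECS
    selectors: tuple[str, ...] = ("cars", "frog", "uve")
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    stratify: bool = True
    normalize: bool = True
    cars: CarsConfig = CarsConfig()
    frog: FrogConfig = FrogConfig()
    uve: UveConfig = UveConfig()


@dataclass
class EvaluationReport:
    """Grid results: one row per (element, model, selector state).

    ``predictions`` stores, per cell, the reference and predicted values of
    each subset so every metric row can be recomputed; ``selections`` keeps
    the per-(element, selector) channel choices and diagnostics.
    """

    table: pd.DataFrame
    predictions: dict
    selections: dict
    split: SplitIndices
    seed: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def recompute_row(self, element: str, model: str, selector: str) -> dict:
        """Metrics recomputed from stored predictions (self-consistency)."""
        cell = self.predictions[(element, model, selector)]
        out = {}
        for subset in ("calibration", "validation", "prediction"):
            y_true, y_pred = cell[subset]
            out[subset] = compute_metrics(y_true, y_pred)
        return out

    def predictions_frame(self) -> pd.DataFrame:
        """All persisted predictions as one long table
        (element, model, selector, subset, reference, predicted)."""
        frames = []
        for (element, model, selector), cell in self.predictions.items():
            for subset in ("calibration", "validation", "prediction"):
                y_true, y_pred = cell[subset]
                frames.append(
                    pd.DataFrame(
                        {
                            "element": element,
                            "model": model,
                            "selector": selector,
                            "subset": subset,
                            "reference": y_true,
                            "predicted": y_pred,
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)

    def scatter_frame(self, element: str, model: str, selector: str) -> pd.DataFrame:
        """Reference-vs-predicted long table (for scatter plots)."""
        cell = self.predictions[(element, model, selector)]
        frames = []
        for subset in ("calibration", "validation", "prediction"):
            y_true, y_pred = cell[subset]
            frames.append(
                pd.DataFrame(
                    {"subset": subset, "reference": y_true, "predicted": y_pred}
                )
            )
        return pd.concat(frames, ignore_index=True)


def _run_selector(name, X_cal, y_cal, config: ExperimentConfig, seed: int) -> SelectionResult:
    import dataclasses

    if name == "cars":
        return cars_select(X_cal, y_cal, dataclasses.replace(config.cars, seed=seed))
    if name == "frog":
        return random_frog_select(X_cal, y_cal, dataclasses.replace(config.frog, seed=seed))
    if name == "uve":
        return uve_select(X_cal, y_cal, dataclasses.replace(config.uve, seed=seed))
    raise ValueError(f"unknown selector {name!r}")


def run_experiment(
    spectra: SpectrumSet,
    concentrations: pd.DataFrame,
    config: ExperimentConfig = ExperimentConfig(),
    seed: int = 0,
) -> EvaluationReport:
    """Normalize, split once, select per element, fit and score every cell.

    Selection is fitted on calibration rows only; the one split is shared by
    the whole grid.  A cell that fails is recorded with its error message
    and skipped rather than aborting the grid.
    """
    if list(concentrations["sample_id"]) != list(spectra.sample_ids):
        raise ValueError("concentration table and spectra are not aligned")
    data = area_normalize(spectra) if config.normalize else spectra
    X = data.intensities
    groups = concentrations["group"].to_numpy() if config.stratify else None
    split = split_dataset(
        X.shape[0], config.fractions, seed=derive_seed(seed, "split"), group_labels=groups
    )
    cal, val, pred = split.calibration, split.validation, split.prediction

    rows = []
    predictions: dict = {}
    selections: dict = {}
    for element in config.elements:
        y = concentrations[f"{element}_mgkg"].to_numpy(dtype=float)
        masks: dict[str, np.ndarray | None] = {"full": None}
        for sel_name in config.selectors:
            sel = _run_selector(
                sel_name, X[cal], y[cal], config, derive_seed(seed, sel_name, element)
            )
            selections[(element, sel_name)] = sel
            masks[sel_name] = sel.indices
        for spec in config.model_specs:
            for sel_name, mask in masks.items():
                row = {
                    "element": element,
                    "model": spec.name,
                    "selector": sel_name,
                    "n_variables": X.shape[1] if mask is None else int(mask.size),
                    "seed": seed,
                }
                try:
                    cell_spec = RegressorSpec(
                        spec.name, spec.params, seed=derive_seed(seed, spec.name, element)
                    )
                    model = fit_model(cell_spec, X[cal], y[cal], mask=mask)
                    cell = {}
                    for subset_name, idx in (
                        ("calibration", cal),
                        ("validation", val),
                        ("prediction", pred),
                    ):
                        y_hat = model_predict(model, X[idx])
                        cell[subset_name] = (y[idx], y_hat)
                        m = compute_metrics(y[idx], y_hat)
                        key = {"calibration": "c", "validation": "v", "prediction": "p"}[
                            subset_name
                        ]
                        row[f"r{key}2"] = m.r_squared
                        row[f"rmse{key}"] = m.rmse
                    predictions[(element, spec.name, sel_name)] = cell
                    row["error"] = ""
                except Exception as exc:  # cell failure is recorded, not fatal
                    for key in ("c", "v", "p"):
                        row[f"r{key}2"] = np.nan
                        row[f"rmse{key}"] = np.nan
                    row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)

    table = pd.DataFrame(rows)[
        [
            "element",
            "model",
            "selector",
            "n_variables",
            "rc2",
            "rmsec",
            "rv2",
            "rmsev",
            "rp2",
            "rmsep",
            "seed",
            "error",
        ]
    ]
    return EvaluationReport(
        table=table, predictions=predictions, selections=selections, split=split, seed=seed
    )


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

def descriptive_stats(concentrations: pd.DataFrame) -> pd.DataFrame:
    """Per-(element, group) Min / Max / Mean / Range / Var / Std table.

    Range = Max - Min on unrounded values; Var is the sample variance
    (n-1 denominator) and Std its square root.  Groups of a single sample
    get NaN variance markers.
    """
    elements = [c[: -len("_mgkg")] for c in concentrations.columns if c.endswith("_mgkg")]
    records = []
    for element in elements:
        grouped = concentrations.groupby("group", sort=False)[f"{element}_mgkg"]
        for group, vals in grouped:
            v = vals.to_numpy(dtype=float)
            var = float(np.var(v, ddof=1)) if v.size > 1 else float("nan")
            records.append(
                {
                    "element": element,
                    "group": group,
                    "n": v.size,
                    "Min": float(v.min()),
                    "Max": float(v.max()),
                    "Mean": float(v.mean()),
                    "Range": float(v.max() - v.min()),
                    "Var": var,
                    "Std": float(np.sqrt(var)) if v.size > 1 else float("nan"),
                }
            )
    return pd.DataFrame(records)
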