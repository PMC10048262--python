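"""Spectrum normalization and calibration/validation/prediction splitting.

Spectra are reduced by area normalization — each spectrum is divided by its
trapezoidal integral over the wavelength axis, so every row has unit area and
point-to-point intensity fluctuations between samples cancel.  Samples are
then partitioned 60 / 28 / 12 % into calibration, validation and prediction
sets; subset sizes follow largest-remainder apportionment and the split can
be stratified by dose group so extreme concentration groups appear in all
three subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import SpectrumSet

__all__ = ["SplitIndices", "area_normalize", "split_dataset", "largest_remainder"]

DEFAULT_FRACTIONS = (0.60, 0.28, 0.12)
SUBSET_NAMES = ("calibration", "validation", "prediction")


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint calibration / validation / prediction index sets."""

    calibration: np.ndarray
    validation: np.ndarray
    prediction: np.ndarray

    def __post_init__(self) -> None:
        sets = [set(self.calibration), set(self.validation), set(self.prediction)]
        total = len(self.calibration) + len(self.validation) + len(self.prediction)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("split subsets are not pairwise disjoint")

    @property
    def n(self) -> int:
        return len(self.calibration) + len(self.validation) + len(self.prediction)

    def as_frame(self, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """(sample_id, subset) table for audit / re-use."""
        idx = np.concatenate([self.calibration, self.validation, self.prediction])
        subset = (
            ["calibration"] * len(self.calibration)
            + ["validation"] * len(self.validation)
            + ["prediction"] * len(self.prediction)
        )
        ids = idx if sample_ids is None else [sample_ids[i] for i in idx]
        out = pd.DataFrame({"sample_id": ids, "subset": subset, "index": idx})
        return out.sort_values("index").reset_index(drop=True)


def area_normalize(spectra: SpectrumSet) -> SpectrumSet:
    """Divide each spectrum by its trapezoidal area over the wavelength axis.

    Output rows integrate to exactly 1; the transform is idempotent and
    removes any per-sample scalar intensity factor.  Rows with non-positive
    total area are rejected by sample id.
    """
    areas = np.trapezoid(spectra.intensities, spectra.wavelengths, axis=1)
    bad = np.flatnonzero(areas <= 0)
    if bad.size:
        ids = [spectra.sample_ids[i] for i in bad]
        raise ValueError(f"non-positive spectral area for samples: {ids}")
    return SpectrumSet(
        wavelengths=spectra.wavelengths,
        intensities=spectra.intensities / areas[:, None],
        sample_ids=list(spectra.sample_ids),
    )


def largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer subset sizes summing to n, by largest-remainder apportionment.

    Ties in the remainder are broken in favour of the earlier subset.
    """
    quotas = [n * f for f in fractions]
    sizes = [int(np.floor(q)) for q in quotas]
    shortfall = n - sum(sizes)
    order = sorted(
        range(len(fractions)), key=lambda i: (-(quotas[i] - sizes[i]), i)
    )
    for i in order[:shortfall]:
        sizes[i] += 1
    return sizes


def _stratified_cells(
    group_sizes: list[int], totals: list[int], fractions: Sequence[float]
) -> np.ndarray:
    """Per-(group, subset) counts with exact row sums (group sizes) and
    column sums (global largest-remainder totals): controlled rounding of the
    fractional quotas by floors plus greedy largest-remainder allocation."""
    g, s = len(group_sizes), len(totals)
    quotas = np.array([[ng * f for f in fractions] for ng in group_sizes])
    cells = np.floor(quotas).astype(int)
    row_def = np.array(group_sizes) - cells.sum(axis=1)
    col_def = np.array(totals) - cells.sum(axis=0)
    # place one unit at a time at the (group, subset) with the largest
    # remainder among cells whose row and column still have a deficit
    rem = quotas - np.floor(quotas)
    order = np.dstack(np.unravel_index(np.argsort(-rem, axis=None), rem.shape))[0]
    while row_def.sum() > 0:
        placed = False
        for gi, si in order:
            if row_def[gi] > 0 and col_def[si] > 0:
                cells[gi, si] += 1
                row_def[gi] -= 1
                col_def[si] -= 1
                placed = True
                break
        if not placed:  # cannot happen: deficits always admit a cell
            raise RuntimeError("stratified apportionment failed")
    return cells


def split_dataset(
    n: int,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
    group_labels: Sequence | None = None,
) -> SplitIndices:
    """Random calibration / validation / prediction partition.

    Subset totals always follow global largest-remainder apportionment of
    ``n * fractions`` (e.g. n=288 at 60/28/12 % gives 173/81/34).  When
    ``group_labels`` is given the split is stratified: per-group cell counts
    are a controlled rounding of the group quotas under those fixed totals,
    and samples are shuffled within groups.  The result depends only on
    (n, fractions, seed, group order), not on sample names.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    if n < len(fractions):
        raise ValueError(f"need at least {len(fractions)} samples, got {n}")

    totals = largest_remainder(n, fractions)
    rng = np.random.default_rng(seed)

    if group_labels is None:
        perm = rng.permutation(n)
        bounds = np.cumsum(totals)
        parts = np.split(perm, bounds[:-1])
    else:
        if len(group_labels) != n:
            raise ValueError("group_labels length must equal n")
        labels = np.asarray(group_labels)
        uniq = list(dict.fromkeys(labels))  # first-appearance order
        group_idx = [np.flatnonzero(labels == u) for u in uniq]
        cells = _stratified_cells([len(ix) for ix in group_idx], totals, fractions)
        parts = [[] for _ in totals]
        for gi, ix in enumerate(group_idx):
            shuffled = rng.permutation(ix)
            start = 0
            for si in range(len(totals)):
                parts[si].append(shuffled[start : start + cells[gi, si]])
                start += cells[gi, si]
        parts = [np.concatenate(p) if p else np.array([], dtype=int) for p in parts]

    return SplitIndices(
        calibration=np.sort(parts[0]),
        validation=np.sort(parts[1]),
        prediction=np.sort(parts[2]),
    )
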