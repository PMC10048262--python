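"""Synthetic LIBS dataset generator with known ground truth.

Emulates a laser-induced breakdown spectroscopy (LIBS) experiment on
heavy-metal-spiked plant pellets: a concentration design of 8 dose groups
(one control + seven treatments, 36 pellets each, 288 samples total,
12 plant varieties assigned cyclically), and for every pellet an emission
spectrum on a 200-1000 nm axis built from Gaussian analyte lines whose
areas are proportional to the Cd / Cu / Pb content, plus
concentration-independent matrix lines, a flat continuum baseline, and
per-shot noise. Each sample's spectrum is the average of ``n_shots``
single-shot spectra (default 80, mirroring a 4 x 4 crater array with 5
accumulations per crater).

Everything is deterministic given a seed, so downstream wavelength
selection and regression can be validated against the known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LineLibrary",
    "SimConfig",
    "SpectrumSet",
    "DEFAULT_LINE_LIBRARY",
    "DEFAULT_GROUP_MEANS",
    "DEFAULT_GROUP_SDS",
    "VARIETY_LABELS",
    "generate_design",
    "synthesize_spectrum",
    "generate_dataset",
    "concentrations_to_csv",
    "concentrations_from_csv",
]

ELEMENTS = ("Cd", "Cu", "Pb")

#: Analyte emission lines (element, center in nm, relative strength).
#: Cd has six usable lines in the visible/UV, Cu the close 324.09/324.79 nm
#: doublet (deliberately overlapping at the default peak width, to exercise
#: the strong channel covariance typical of LIBS), Pb three lines.
DEFAULT_ANALYTE_LINES: tuple[tuple[str, float, float], ...] = (
    ("Cd", 214.44, 1.0),
    ("Cd", 226.50, 1.0),
    ("Cd", 441.56, 1.0),
    ("Cd", 467.90, 1.0),
    ("Cd", 573.80, 1.0),
    ("Cd", 643.85, 1.0),
    ("Cu", 324.09, 1.0),
    ("Cu", 324.79, 1.0),
    ("Pb", 280.00, 1.0),
    ("Pb", 404.00, 1.0),
    ("Pb", 405.70, 1.0),
)

#: Per-group mean concentration (mg kg^-1) of the dosing design, group 0 being
#: the uncontaminated control.  Values follow the descriptive statistics of an
#: ICP-MS-referenced contamination experiment on Fritillaria pellets.
DEFAULT_GROUP_MEANS: dict[str, tuple[float, ...]] = {
    "Cu": (2.50, 20.06, 37.31, 52.48, 65.95, 79.66, 172.57, 215.06),
    "Cd": (0.43, 5.86, 10.64, 22.87, 26.39, 60.32, 82.48, 93.91),
    "Pb": (0.29, 6.06, 22.75, 51.58, 65.62, 85.00, 112.26, 199.24),
}

#: Matching per-group standard deviations (mg kg^-1).
DEFAULT_GROUP_SDS: dict[str, tuple[float, ...]] = {
    "Cu": (1.09, 3.62, 6.05, 6.13, 4.10, 4.50, 22.74, 27.82),
    "Cd": (0.28, 0.46, 0.56, 1.53, 1.31, 19.85, 13.24, 5.94),
    "Pb": (0.19, 0.74, 0.80, 16.29, 3.81, 7.71, 7.99, 24.58),
}

VARIETY_LABELS: tuple[str, ...] = tuple(f"var{i:02d}" for i in range(1, 13))

#: Matrix (non-analyte) decoy lines: (center nm, area intensity).  Strong
#: plant-matrix emitters (Mg, Ca, H, Na, K) whose intensity does not depend on
#: the analyte dose — selectors must learn to reject these channels.
DEFAULT_MATRIX_LINES: tuple[tuple[float, float], ...] = (
    (285.21, 400.0),   # Mg I
    (393.37, 800.0),   # Ca II
    (422.67, 600.0),   # Ca I
    (589.00, 500.0),   # Na I
    (656.28, 300.0),   # H alpha
    (766.49, 500.0),   # K I
)


@dataclass(frozen=True)
class LineLibrary:
    """Catalogue of analyte emission lines.

    Each entry is ``(element, center_nm, relative_strength)`` with strictly
    positive strength; every element must contribute at least one line.
    """

    entries: tuple[tuple[str, float, float], ...] = DEFAULT_ANALYTE_LINES

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("line library is empty")
        for element, center, strength in self.entries:
            if strength <= 0:
                raise ValueError(
                    f"line {element} {center} nm has non-positive strength {strength}"
                )

    @property
    def elements(self) -> tuple[str, ...]:
        seen: list[str] = []
        for element, _, _ in self.entries:
            if element not in seen:
                seen.append(element)
        return tuple(seen)

    def lines_for(self, element: str) -> list[tuple[float, float]]:
        """(center, strength) pairs for one element."""
        lines = [(c, s) for e, c, s in self.entries if e == element]
        if not lines:
            raise KeyError(f"no emission lines for element {element!r}")
        return lines

    def check_within(self, wl_min: float, wl_max: float) -> None:
        for element, center, _ in self.entries:
            if not (wl_min < center < wl_max):
                raise ValueError(
                    f"line {element} {center} nm lies outside the "
                    f"wavelength axis ({wl_min}-{wl_max} nm)"
                )


DEFAULT_LINE_LIBRARY = LineLibrary()


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated experiment.

    Defaults reproduce the study conditions: 8 groups x 36 pellets,
    group means/sds per the dosing design, a 200-1000 nm axis at 0.5 nm
    (1601 channels), 0.3 nm Gaussian line width, and 80 averaged shots.
    """

    n_groups: int = 8
    n_per_group: int = 36
    group_means: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MEANS)
    )
    group_sds: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SDS)
    )
    wl_start: float = 200.0
    wl_stop: float = 1000.0
    wl_step: float = 0.5
    sigma: float = 0.3                      # Gaussian line width, nm
    sensitivity: Mapping[str, float] = field(
        default_factory=lambda: {"Cd": 0.04, "Cu": 0.04, "Pb": 0.04}
    )                                       # peak area per mg kg^-1; trace
    # regime: analyte peaks a few percent of the continuum, so per-channel
    # shot noise is a real error source and line redundancy matters
    matrix_lines: tuple[tuple[float, float], ...] = DEFAULT_MATRIX_LINES
    baseline: float = 100.0                 # flat continuum level
    additive_noise_sd: float = 2.0          # per-channel detector noise
    shot_noise_sd: float = 0.1              # per-shot multiplicative fluctuation
    n_shots: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.n_per_group < 1:
            raise ValueError("n_groups and n_per_group must be positive")
        if self.wl_step <= 0:
            raise ValueError("wavelength step must be > 0")
        if self.wl_stop <= self.wl_start:
            raise ValueError("wavelength stop must exceed start")
        if self.sigma <= 0:
            raise ValueError("peak width sigma must be > 0")
        if self.additive_noise_sd < 0 or self.shot_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_shots < 1:
            raise ValueError("n_shots must be >= 1")
        for element, sds in self.group_sds.items():
            if any(s < 0 for s in sds):
                raise ValueError(f"negative group sd for {element}")
        for element in self.group_means:
            if len(self.group_means[element]) < self.n_groups:
                raise ValueError(
                    f"{element}: need >= {self.n_groups} group means, "
                    f"got {len(self.group_means[element])}"
                )
            if len(self.group_sds[element]) < self.n_groups:
                raise ValueError(
                    f"{element}: need >= {self.n_groups} group sds, "
                    f"got {len(self.group_sds[element])}"
                )

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self.group_means)

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.wl_stop - self.wl_start) / self.wl_step)) + 1
        return self.wl_start + self.wl_step * np.arange(n)

    def with_(self, **kwargs) -> "SimConfig":
        """Copy with fields replaced (convenience for tests/CLI)."""
        return replace(self, **kwargs)


@dataclass
class SpectrumSet:
    """Wavelength axis + intensity matrix + sample ids (pipeline currency)."""

    wavelengths: np.ndarray        # (p,), strictly increasing, nm
    intensities: np.ndarray        # (n, p), arbitrary units
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        if self.intensities.shape[1] != self.wavelengths.shape[0]:
            raise ValueError(
                f"column count {self.intensities.shape[1]} does not match "
                f"wavelength axis length {self.wavelengths.shape[0]}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain missing/non-finite values")
        if len(self.sample_ids) != self.intensities.shape[0]:
            raise ValueError("sample id count does not match row count")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.wavelengths.shape[0]

    def to_csv(self, path) -> None:
        """Wide CSV: first column sample_id, header = wavelengths (2 dp)."""
        df = pd.DataFrame(
            self.intensities,
            columns=[f"{w:.2f}" for w in self.wavelengths],
        )
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectrumSet":
        df = pd.read_csv(path)
        if df.columns[0] != "sample_id":
            raise ValueError("first column of a spectrum CSV must be sample_id")
        wavelengths = np.array([float(c) for c in df.columns[1:]])
        return cls(
            wavelengths=wavelengths,
            intensities=df.iloc[:, 1:].to_numpy(dtype=float),
            sample_ids=[str(s) for s in df["sample_id"]],
        )


# ---------------------------------------------------------------------------
# concentration design
# ---------------------------------------------------------------------------

def generate_design(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw the per-sample concentration table for the dosing design.

    Each group's concentrations come from a normal distribution with the
    configured group mean and sd, truncated at zero (negative draws are
    clipped).  Varieties cycle through the 12 labels.  Returns a DataFrame
    with columns ``sample_id, group, variety, <El>_mgkg`` per element.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows: dict[str, list] = {"sample_id": [], "group": [], "variety": []}
    for element in config.elements:
        rows[f"{element}_mgkg"] = []

    k = 0
    for g in range(config.n_groups):
        label = "CK" if g == 0 else f"T{g}"
        draws = {
            element: np.clip(
                rng.normal(
                    config.group_means[element][g],
                    config.group_sds[element][g],
                    config.n_per_group,
                ),
                0.0,
                None,
            )
            for element in config.elements
        }
        for j in range(config.n_per_group):
            rows["sample_id"].append(f"S{k + 1:03d}")
            rows["group"].append(label)
            rows["variety"].append(VARIETY_LABELS[k % len(VARIETY_LABELS)])
            for element in config.elements:
                rows[f"{element}_mgkg"].append(float(draws[element][j]))
            k += 1
    return pd.DataFrame(rows)


def concentrations_to_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def concentrations_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "group", "variety"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"concentration CSV missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# spectrum synthesis
# ---------------------------------------------------------------------------

def _gaussian_profile(wavelengths: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """Unit-area Gaussian line profile evaluated on the axis."""
    z = (wavelengths - center) / sigma
    return np.exp(-0.5 * z * z) / (sigma * np.sqrt(2.0 * np.pi))


def _noise_free_signal(
    concentrations: Mapping[str, float],
    lines: LineLibrary,
    config: SimConfig,
) -> np.ndarray:
    wl = config.wavelengths
    lines.check_within(wl[0], wl[-1])
    signal = np.full(wl.shape, config.baseline, dtype=float)
    for element in lines.elements:
        if element not in concentrations:
            raise KeyError(f"no concentration given for analyte {element}")
        conc = concentrations[element]
        sens = config.sensitivity[element]
        for center, strength in lines.lines_for(element):
            signal += strength * sens * conc * _gaussian_profile(wl, center, config.sigma)
    for center, area in config.matrix_lines:
        if not (wl[0] < center < wl[-1]):
            raise ValueError(f"matrix line {center} nm outside the wavelength axis")
        signal += area * _gaussian_profile(wl, center, config.sigma)
    return signal


def synthesize_spectrum(
    concentrations: Mapping[str, float],
    lines: LineLibrary,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One single-shot spectrum for a sample with the given contents.

    intensity(lambda) = [baseline
                         + sum_lines strength * sensitivity * conc * G(lambda)
                         + matrix terms] * (1 + eps(lambda)) + delta(lambda),
    clipped at zero; G is a unit-area Gaussian, eps ~ N(0, shot sd) is the
    per-channel multiplicative shot fluctuation (point-to-point plasma
    variability — deliberately not a scalar, which area normalization would
    cancel exactly), delta ~ N(0, additive sd) is detector noise.
    """
    signal = _noise_free_signal(concentrations, lines, config)
    shot = (
        rng.normal(0.0, config.shot_noise_sd, signal.shape)
        if config.shot_noise_sd > 0
        else 0.0
    )
    additive = (
        rng.normal(0.0, config.additive_noise_sd, signal.shape)
        if config.additive_noise_sd > 0
        else 0.0
    )
    return np.clip(signal * (1.0 + shot) + additive, 0.0, None)


def generate_dataset(
    config: SimConfig,
    seed: int | None = None,
    lines: LineLibrary = DEFAULT_LINE_LIBRARY,
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Full synthetic dataset: design + shot-averaged spectra.

    Per sample, ``n_shots`` single-shot spectra are synthesized (vectorized
    over shots: one scalar shot factor and one additive-noise vector each)
    and averaged into one row. Identical seed => bit-identical output.
    """
    seed = config.seed if seed is None else seed
    design = generate_design(config, seed)
    rng = np.random.default_rng((seed, 1))  # distinct stream from the design
    wl = config.wavelengths
    n = len(design)
    intensities = np.empty((n, wl.shape[0]))
    conc_cols = {el: design[f"{el}_mgkg"].to_numpy() for el in config.elements}
    for i in range(n):
        conc = {el: conc_cols[el][i] for el in config.elements}
        signal = _noise_free_signal(conc, lines, config)
        shot = (
            rng.normal(0.0, config.shot_noise_sd, (config.n_shots, wl.shape[0]))
            if config.shot_noise_sd > 0
            else np.zeros((config.n_shots, 1))
        )
        additive = (
            rng.normal(0.0, config.additive_noise_sd, (config.n_shots, wl.shape[0]))
            if config.additive_noise_sd > 0
            else 0.0
        )
        shots = np.clip(signal[None, :] * (1.0 + shot) + additive, 0.0, None)
        intensities[i] = shots.mean(axis=0)
    spectra = SpectrumSet(
        wavelengths=wl,
        intensities=intensities,
        sample_ids=list(design["sample_id"]),
    )
    return spectra, design
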