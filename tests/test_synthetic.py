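"""Synthetic LIBS generator: design statistics, spectral physics, determinism."""

import numpy as np
import pytest
from scipy import stats

from libsquant import (
    DEFAULT_LINE_LIBRARY,
    LineLibrary,
    SimConfig,
    SpectrumSet,
    generate_dataset,
    generate_design,
    synthesize_spectrum,
)
from libsquant.synthetic import DEFAULT_GROUP_MEANS, VARIETY_LABELS

CD_LINES = [214.44, 226.50, 441.56, 467.90, 573.80, 643.85]


class TestDesign:
    def test_default_design_is_288_samples_in_8_groups_of_36(self):
        design = generate_design(SimConfig(), seed=0)
        assert len(design) == 288
        counts = design.groupby("group").size()
        assert len(counts) == 8 and (counts == 36).all()
        assert set(design["variety"]) == set(VARIETY_LABELS)
        # varieties cycle, so every group sees every variety three times
        assert (design.groupby(["group", "variety"]).size() == 3).all()

    def test_control_group_sits_below_every_treatment_mean(self):
        design = generate_design(SimConfig(), seed=3)
        for el in ("Cd", "Cu", "Pb"):
            ck = design.loc[design.group == "CK", f"{el}_mgkg"]
            treat_means = design[design.group != "CK"].groupby("group")[f"{el}_mgkg"].mean()
            assert (ck < treat_means.min()).all()

    def test_group_sample_means_track_configured_targets(self):
        """Pooled over 20 seeds, each Cd group mean matches the analytic
        mean of the zero-truncated normal within 3 pooled standard errors."""
        cfg = SimConfig()
        pooled = {g: [] for g in range(8)}
        for seed in range(20):
            design = generate_design(cfg, seed=seed)
            for g, (_, grp) in enumerate(design.groupby("group", sort=False)):
                pooled[g].extend(grp["Cd_mgkg"])
        for g in range(8):
            mu = DEFAULT_GROUP_MEANS["Cd"][g]
            sd = cfg.group_sds["Cd"][g]
            # clip-at-zero normal: E = mu*Phi(mu/sd) + sd*phi(mu/sd)
            z = mu / sd
            expected = mu * stats.norm.cdf(z) + sd * stats.norm.pdf(z)
            vals = np.array(pooled[g])
            se = vals.std(ddof=1) / np.sqrt(vals.size)
            assert abs(vals.mean() - expected) < 3 * se

    def test_zero_sd_collapses_each_group_onto_its_mean(self):
        cfg = SimConfig(
            n_per_group=4,
            group_sds={el: (0.0,) * 8 for el in ("Cd", "Cu", "Pb")},
        )
        design = generate_design(cfg, seed=1)
        for el in ("Cd", "Cu", "Pb"):
            got = design.groupby("group", sort=False)[f"{el}_mgkg"].agg(["min", "max"])
            assert np.allclose(got["min"], got["max"])
            assert np.allclose(
                got["min"].to_numpy(), DEFAULT_GROUP_MEANS[el][:8]
            )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_per_group=0)
        with pytest.raises(ValueError):
            SimConfig(group_sds={**SimConfig().group_sds, "Cd": (-1.0,) * 8})
        with pytest.raises(ValueError):
            SimConfig(wl_step=0.0)
        with pytest.raises(ValueError):
            SimConfig(n_shots=0)


class TestSpectrum:
    def _quiet(self, **kw):
        return SimConfig(
            additive_noise_sd=0.0, shot_noise_sd=0.0, matrix_lines=(), **kw
        )

    def test_null_signal_is_flat_baseline(self, rng):
        cfg = self._quiet()
        spec = synthesize_spectrum(
            {"Cd": 0.0, "Cu": 0.0, "Pb": 0.0}, DEFAULT_LINE_LIBRARY, cfg, rng
        )
        assert np.allclose(spec, cfg.baseline)

    def test_cd_lines_appear_as_local_maxima_at_nearest_channels(self, rng):
        cfg = self._quiet()
        spec = synthesize_spectrum(
            {"Cd": 50.0, "Cu": 0.0, "Pb": 0.0}, DEFAULT_LINE_LIBRARY, cfg, rng
        )
        wl = cfg.wavelengths
        for center in CD_LINES:
            j = int(np.argmin(np.abs(wl - center)))
            assert spec[j] > spec[j - 1] and spec[j] > spec[j + 1], center

    def test_peak_area_is_proportional_to_concentration(self, rng):
        """Baseline-subtracted trapezoidal area of an isolated line doubles
        exactly with concentration (zero-noise linearity)."""
        cfg = self._quiet()
        lines = LineLibrary((("Cd", 441.56, 1.0),))
        wl = cfg.wavelengths
        window = np.abs(wl - 441.56) < 5.0
        areas = {}
        for conc in (25.0, 50.0):
            spec = synthesize_spectrum({"Cd": conc}, lines, cfg, rng)
            areas[conc] = np.trapezoid(spec[window] - cfg.baseline, wl[window])
        assert areas[50.0] == pytest.approx(2 * areas[25.0], rel=1e-6)
        # the absolute area matches sensitivity * concentration up to grid
        # quadrature error (0.5 nm trapezoid of a 0.3 nm-sigma line)
        assert areas[50.0] == pytest.approx(cfg.sensitivity["Cd"] * 50.0, rel=5e-3)

    def test_line_outside_axis_rejected(self, rng):
        cfg = self._quiet()
        bad = LineLibrary((("Cd", 1500.0, 1.0),))
        with pytest.raises(ValueError, match="outside"):
            synthesize_spectrum({"Cd": 1.0}, bad, cfg, rng)
        with pytest.raises(ValueError):
            LineLibrary((("Cd", 441.56, -1.0),))


class TestDataset:
    def test_default_dataset_shape(self):
        cfg = SimConfig(n_shots=2)  # shape contract only; keep it quick
        spectra, conc = generate_dataset(cfg, seed=0)
        assert spectra.intensities.shape == (288, 1601)
        assert spectra.wavelengths[0] == 200.0 and spectra.wavelengths[-1] == 1000.0
        assert list(conc["sample_id"]) == spectra.sample_ids

    def test_same_seed_bit_identical_different_seed_not(self, small_config):
        a1, c1 = generate_dataset(small_config, seed=11)
        a2, c2 = generate_dataset(small_config, seed=11)
        b, _ = generate_dataset(small_config, seed=12)
        assert np.array_equal(a1.intensities, a2.intensities)
        assert c1.equals(c2)
        assert not np.array_equal(a1.intensities, b.intensities)

    def test_shot_averaging_reduces_channel_variance(self):
        """Per-channel sd of the 80-shot average is ~ 1/sqrt(80) of the
        single-shot sd (Monte-Carlo estimate over 150 repeats)."""
        base = dict(
            n_groups=1,
            n_per_group=1,
            group_means={el: (50.0,) for el in ("Cd", "Cu", "Pb")},
            group_sds={el: (0.0,) for el in ("Cd", "Cu", "Pb")},
            wl_stop=250.0,
            matrix_lines=(),
        )
        lines = LineLibrary((("Cd", 214.44, 1.0),))
        reps = 150
        sds = {}
        for k in (1, 80):
            cfg = SimConfig(n_shots=k, **base)
            rows = np.stack(
                [
                    generate_dataset(cfg, seed=s, lines=lines)[0].intensities[0]
                    for s in range(reps)
                ]
            )
            sds[k] = rows.std(axis=0, ddof=1).mean()
        ratio = sds[1] / sds[80]
        assert np.sqrt(80) * 0.8 < ratio < np.sqrt(80) * 1.2

    def test_csv_round_trip(self, tmp_path, small_config):
        spectra, _ = generate_dataset(small_config, seed=5)
        path = tmp_path / "spectra.csv"
        spectra.to_csv(path)
        back = SpectrumSet.from_csv(path)
        assert np.array_equal(back.wavelengths, spectra.wavelengths)
        assert back.sample_ids == spectra.sample_ids
        np.testing.assert_allclose(back.intensities, spectra.intensities, rtol=1e-12)

    def test_spectrum_set_validation(self):
        with pytest.raises(ValueError, match="wavelength"):
            SpectrumSet(np.array([1.0, 1.0, 2.0]), np.ones((2, 3)), ["a", "b"])
        with pytest.raises(ValueError, match="column count"):
            SpectrumSet(np.array([1.0, 2.0]), np.ones((2, 3)), ["a", "b"])
        with pytest.raises(ValueError, match="unique"):
            SpectrumSet(np.array([1.0, 2.0]), np.ones((2, 2)), ["a", "a"])
        with pytest.raises(ValueError, match="finite|missing"):
            SpectrumSet(np.array([1.0, 2.0]), np.array([[1.0, np.nan]]), ["a"])
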