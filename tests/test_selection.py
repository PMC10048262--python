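"""CARS, random frog and UVE on fixtures with known informative channels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from libsquant import (
    CarsConfig,
    FrogConfig,
    UveConfig,
    cars_select,
    edf_schedule,
    random_frog_select,
    uve_select,
)

INFORMATIVE = (5, 17, 29)


def make_fixture(seed, n=40, p=60, noise=0.05):
    """Random spectra-like matrix where y depends on three channels."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = X[:, INFORMATIVE].sum(axis=1) + rng.normal(0, noise, n)
    return X, y


class TestEdfSchedule:
    def test_closed_form_endpoints(self):
        r = edf_schedule(200, 50)
        assert r[0] == pytest.approx(1.0, abs=1e-12)
        assert r[-1] == pytest.approx(0.01, abs=1e-12)

    def test_two_run_schedule(self):
        np.testing.assert_allclose(edf_schedule(4, 2), [1.0, 0.5], atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(p=st.integers(3, 3000), N=st.integers(2, 100))
    def test_strictly_decreasing_with_pinned_endpoints(self, p, N):
        r = edf_schedule(p, N)
        assert len(r) == N
        assert np.all(np.diff(r) < 0)
        assert r[0] == pytest.approx(1.0, abs=1e-9)
        assert r[-1] == pytest.approx(2.0 / p, rel=1e-9)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            edf_schedule(2, 10)
        with pytest.raises(ValueError):
            edf_schedule(100, 1)


class TestCars:
    def test_subset_sizes_nonincreasing_and_bounded_by_edf(self):
        X, y = make_fixture(0)
        res = cars_select(X, y, CarsConfig(n_runs=20, seed=1))
        sizes = res.diagnostics["subset_sizes"]
        caps = res.diagnostics["edf_caps"]
        assert np.all(np.diff(sizes) <= 0)
        assert np.all(sizes <= caps)

    def test_returned_subset_attains_minimum_rmsecv(self):
        X, y = make_fixture(1)
        res = cars_select(X, y, CarsConfig(n_runs=20, seed=2))
        trace = res.diagnostics["rmsecv_trace"]
        best = res.diagnostics["best_run"]
        assert res.diagnostics["best_rmsecv"] == trace.min()
        assert trace[best] == trace.min()
        # selection never loses to the near-full-spectrum first run
        assert trace.min() <= trace[0]

    def test_recovers_informative_channels(self):
        hits = 0
        for seed in range(5):
            X, y = make_fixture(100 + seed)
            res = cars_select(X, y, CarsConfig(n_runs=25, seed=seed))
            hits += all(j in res.indices for j in INFORMATIVE)
        assert hits >= 4

    def test_deterministic_given_seed(self):
        X, y = make_fixture(2)
        r1 = cars_select(X, y, CarsConfig(n_runs=15, seed=7))
        r2 = cars_select(X, y, CarsConfig(n_runs=15, seed=7))
        assert np.array_equal(r1.indices, r2.indices)
        np.testing.assert_array_equal(
            r1.diagnostics["rmsecv_trace"], r2.diagnostics["rmsecv_trace"]
        )


class TestRandomFrog:
    def test_counting_identity_and_probability_bounds(self):
        X, y = make_fixture(3)
        res = random_frog_select(X, y, FrogConfig(n_iterations=200, seed=4))
        d = res.diagnostics
        assert d["counts"].sum() == d["subset_size_trace"].sum()
        P = d["probabilities"]
        assert np.all((0.0 <= P) & (P <= 1.0))
        np.testing.assert_allclose(P, d["counts"] / d["n_iterations"])

    def test_probability_bounds_attained_in_forced_cases(self):
        # single-channel problem: the subset is always {0}, so P_0 = 1
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 1))
        y = X[:, 0] + rng.normal(0, 0.1, 20)
        res = random_frog_select(X, y, FrogConfig(n_iterations=50, seed=0))
        assert res.diagnostics["probabilities"][0] == 1.0
        # wide problem, few iterations: channels never touched have P_j = 0
        X, y = make_fixture(4, p=80)
        res = random_frog_select(X, y, FrogConfig(n_iterations=100, seed=1))
        assert np.any(res.diagnostics["probabilities"] == 0.0)

    def test_informative_channels_get_higher_probability(self):
        wins = 0
        for seed in range(5):
            X, y = make_fixture(200 + seed)
            res = random_frog_select(X, y, FrogConfig(n_iterations=300, seed=seed))
            P = res.diagnostics["probabilities"]
            rest = np.setdiff1d(np.arange(X.shape[1]), INFORMATIVE)
            wins += P[list(INFORMATIVE)].mean() > P[rest].mean()
        assert wins >= 4

    def test_deterministic_given_seed(self):
        X, y = make_fixture(5)
        r1 = random_frog_select(X, y, FrogConfig(n_iterations=150, seed=9))
        r2 = random_frog_select(X, y, FrogConfig(n_iterations=150, seed=9))
        assert np.array_equal(r1.indices, r2.indices)
        np.testing.assert_array_equal(
            r1.diagnostics["probabilities"], r2.diagnostics["probabilities"]
        )

    def test_threshold_rule(self):
        X, y = make_fixture(6)
        res = random_frog_select(
            X, y,
            FrogConfig(n_iterations=200, seed=3, selection_rule="threshold",
                       probability_threshold=0.8),
        )
        P = res.diagnostics["probabilities"]
        assert np.array_equal(res.indices, np.flatnonzero(P >= 0.8))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FrogConfig(eta=0.0)
        with pytest.raises(ValueError):
            FrogConfig(theta=-1.0)
        with pytest.raises(ValueError):
            FrogConfig(selection_rule="nope")


class TestUve:
    def test_single_informative_channel_always_retained(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 30))
            y = X[:, 3] + rng.normal(0, 0.01, 40)
            res = uve_select(X, y, UveConfig(seed=seed))
            assert 3 in res.indices, seed

    def test_null_response_retains_few_channels(self):
        fractions = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(50, 100))
            y = rng.normal(size=50)  # independent of X
            res = uve_select(X, y, UveConfig(seed=seed, n_components=2))
            fractions.append(res.n_selected / 100)
        assert np.mean(fractions) <= 0.05

    def test_retained_channels_beat_cutoff_and_exclude_noise_block(self):
        X, y = make_fixture(7)
        res = uve_select(X, y, UveConfig(seed=0))
        c = np.abs(res.diagnostics["stability_real"])
        assert np.all(c[res.indices] > res.diagnostics["cutoff"])
        assert res.indices.max() < X.shape[1]  # noise columns can never appear

    def test_noise_amplitude_is_scale_free(self):
        X, y = make_fixture(8)
        r1 = uve_select(X, y, UveConfig(seed=5, noise_amplitude=1e-10))
        r2 = uve_select(X, y, UveConfig(seed=5, noise_amplitude=2e-10))
        assert np.array_equal(r1.indices, r2.indices)

    def test_column_permutation_equivariance(self):
        X, y = make_fixture(9)
        rng = np.random.default_rng(0)
        perm = rng.permutation(X.shape[1])
        r1 = uve_select(X, y, UveConfig(seed=6))
        r2 = uve_select(X[:, perm], y, UveConfig(seed=6))
        # channel j of the original appears iff its new position appears
        mapped = np.sort(perm[r2.indices])
        assert np.array_equal(np.sort(r1.indices), mapped)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            UveConfig(noise_amplitude=0.0)
        with pytest.raises(ValueError):
            UveConfig(cutoff_quantile=1.5)
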