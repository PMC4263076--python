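import math

import numpy as np
import pytest

import brainglass as bg
from brainglass.metrics import (
    dispersion_from_cc,
    lifetimes_from_cc,
    state_correlation_matrix,
)
from brainglass.repertoire import similarity_matrix


def _traj_from_states(states, T=1.0):
    states = np.asarray(states, dtype=np.int8)
    return bg.Trajectory(
        states=states,
        sweep_index=np.arange(states.shape[0]),
        config=bg.SimulationConfig(T=T, n_steps=states.shape[0] - 1, seed=0),
    )


class TestStateCorrelation:
    def test_identity_and_flip(self):
        s = np.array([1, -1, 1, 1], dtype=np.int8)
        assert bg.state_correlation(s, s) == 1.0
        assert bg.state_correlation(s, -s) == -1.0

    def test_orthogonal_patterns(self):
        s1 = np.array([1, 1, -1, -1], dtype=np.int8)
        s2 = np.array([1, -1, -1, 1], dtype=np.int8)
        assert bg.state_correlation(s1, s2) == pytest.approx(0.0)

    def test_constant_patterns(self):
        up = np.ones(4, dtype=np.int8)
        assert bg.state_correlation(up, up) == 1.0
        assert bg.state_correlation(up, -up) == -1.0
        assert bg.state_correlation(up, np.array([1, -1, 1, -1])) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bg.state_correlation(np.ones(3), np.ones(4))


class TestLaggedSeries:
    def test_absorbing_trajectory_all_ones(self):
        s = np.array([1, -1, 1, 1], dtype=np.int8)
        traj = _traj_from_states(np.tile(s, (10, 1)))
        series = bg.lagged_correlation_series(traj, lag=1)
        assert np.allclose(series.values, 1.0)

    def test_alternating_flip_gives_minus_one(self):
        s = np.array([1, -1, 1, -1, 1], dtype=np.int8)
        states = np.array([s if t % 2 == 0 else -s for t in range(8)])
        series = bg.lagged_correlation_series(_traj_from_states(states), lag=1)
        assert np.allclose(series.values, -1.0)

    @pytest.mark.parametrize("lag,burn_in", [(1, 0), (2, 0), (3, 2), (1, 5)])
    def test_series_length_contract(self, lag, burn_in, rng):
        states = (rng.random((20, 6)) < 0.5) * 2 - 1
        series = bg.lagged_correlation_series(
            _traj_from_states(states), lag=lag, burn_in=burn_in
        )
        assert series.values.size == 20 - lag - burn_in

    def test_lag_too_large(self):
        states = np.ones((3, 4), dtype=np.int8)
        with pytest.raises(ValueError):
            bg.lagged_correlation_series(_traj_from_states(states), lag=3)

    def test_full_correlation_matrix_exposed(self, rng):
        states = (rng.random((12, 8)) < 0.5) * 2 - 1
        M = state_correlation_matrix(_traj_from_states(states))
        assert M.shape == (12, 12)
        assert np.allclose(np.diag(M), 1.0)
        assert np.allclose(M, M.T)


class TestHomogeneityIndex:
    def test_hand_calculation(self):
        # mean 0.5, sample SD sqrt(0.02) ~ 0.1414 => H ~ 3.536
        assert bg.homogeneity_index(np.array([0.4, 0.6])) == pytest.approx(
            0.5 / math.sqrt(0.02), rel=1e-12
        )
        assert bg.homogeneity_index(np.array([0.4, 0.6])) == pytest.approx(3.536, abs=5e-4)

    def test_constant_series_undefined(self):
        assert math.isnan(bg.homogeneity_index(np.full(5, 0.7)))

    def test_scale_invariance(self, rng):
        v = rng.random(50)
        H = bg.homogeneity_index(v)
        assert bg.homogeneity_index(3.7 * v) == pytest.approx(H)

    def test_reversed_trajectory_same_H(self, rng):
        states = ((rng.random((30, 10)) < 0.5) * 2 - 1).astype(np.int8)
        for lag in (1, 3):
            a = bg.homogeneity_index(
                bg.lagged_correlation_series(_traj_from_states(states), lag=lag)
            )
            b = bg.homogeneity_index(
                bg.lagged_correlation_series(_traj_from_states(states[::-1]), lag=lag)
            )
            assert a == pytest.approx(b)


class TestPowerlawSlope:
    def test_exact_reciprocal_decay(self):
        H = {lag: 7.0 / lag for lag in range(1, 21)}
        slope, r2 = bg.powerlaw_slope(H)
        assert slope == pytest.approx(-1.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_H_zero_slope(self):
        slope, _ = bg.powerlaw_slope({lag: 4.2 for lag in (1, 2, 4, 8)})
        assert slope == 0.0

    def test_two_point_hand_algebra(self):
        slope, _ = bg.powerlaw_slope({1: 8.0, 4: 2.0})
        assert slope == pytest.approx(math.log(2 / 8) / math.log(4))
        assert slope == pytest.approx(-1.0)

    def test_nonpositive_H_rejected(self):
        with pytest.raises(ValueError):
            bg.powerlaw_slope({1: 2.0, 2: -0.5})

    def test_lag_range_filters(self):
        H = {1: 8.0, 2: 4.0, 50: 1e9}   # out-of-range lag ignored
        slope, _ = bg.powerlaw_slope(H, lag_range=(1, 20))
        assert slope == pytest.approx(-1.0)


class TestDispersionIndex:
    def test_equal_elements_undefined(self):
        assert math.isnan(dispersion_from_cc(np.full(10, 0.3)))

    def test_uniform_elements_analytic_limit(self):
        rng = np.random.default_rng(0)
        cc = rng.random(200_000)
        assert dispersion_from_cc(cc) == pytest.approx(0.5, abs=0.01)

    def test_binary_elements_hand_calculation(self):
        assert dispersion_from_cc(np.array([0.0, 1.0])) == pytest.approx(1 / 12, rel=1e-12)
        assert dispersion_from_cc(np.array([0.0, 1.0])) == pytest.approx(0.0833, abs=1e-4)

    def test_matches_bruteforce_all_pairs(self, rng):
        states = ((rng.random((60, 12)) < 0.5) * 2 - 1).astype(np.int8)
        D = bg.dispersion_index(_traj_from_states(states), pair_stride=1)
        sim = similarity_matrix(states)
        cc = sim[np.triu_indices(60, k=1)]
        brute = (1 / 12) * np.mean(1 - cc) / cc.var(ddof=1)
        assert D == pytest.approx(brute, rel=1e-12)

    def test_iid_trajectory_mean_cc_near_zero(self, rng):
        n, m = 64, 200
        states = ((rng.random((m, n)) < 0.5) * 2 - 1).astype(np.int8)
        cc1 = bg.lagged_correlation_series(_traj_from_states(states), lag=1).values
        assert abs(cc1.mean()) < 3 / math.sqrt(n * m)

    def test_too_few_states(self):
        with pytest.raises(ValueError):
            bg.dispersion_index(np.ones((2, 5), dtype=np.int8))


class TestLifetimes:
    def test_constant_trajectory_single_lifetime(self):
        s = np.array([1, -1, 1, 1], dtype=np.int8)
        res = bg.metastable_lifetimes(_traj_from_states(np.tile(s, (101, 1))))
        assert res.lifetimes.tolist() == [101]
        assert res.median_lifetime == 101

    def test_all_below_threshold_unit_lifetimes(self, rng):
        # orthogonal-ish random patterns: consecutive cc far below 0.95
        states = ((rng.random((10, 50)) < 0.5) * 2 - 1).astype(np.int8)
        res = bg.metastable_lifetimes(_traj_from_states(states))
        assert res.lifetimes.tolist() == [1] * 10

    def test_hand_run_length_count(self):
        assert lifetimes_from_cc(np.array([1.0, 1.0, 0.0, 1.0]), 0.95).tolist() == [3, 2]

    def test_ms_labelling_only(self):
        s = np.ones(6, dtype=np.int8)
        res = bg.metastable_lifetimes(
            _traj_from_states(np.tile(s, (11, 1))), ms_per_step=10.0
        )
        assert res.median_lifetime_ms == pytest.approx(110.0)


def test_compute_metrics_bundle(small_graph):
    traj = bg.simulate(small_graph, bg.SimulationConfig(T=2.0, n_steps=300, seed=2, burn_in=50))
    m = bg.compute_metrics(traj, lags=(1, 2, 4, 8), ms_per_step=10.0)
    assert set(m.H_by_lag) == {1, 2, 4, 8}
    d = m.to_dict()
    assert d["T"] == 2.0
    assert d["median_lifetime_ms"] == pytest.approx(d["median_lifetime"] * 10)
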