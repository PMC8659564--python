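"""Wavelet approximation and cross-correlation lag alignment."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp
from scipy.signal import periodogram

from emgkin.features import (
    DegenerateSignalError,
    LagProfile,
    LagRangeError,
    apply_lag,
    assemble_design_matrix,
    cross_correlation,
    cross_covariance,
    dwt_approximation,
    estimate_lag,
)
from emgkin.preprocessing import CycleSet


def brute_cross_covariance(y1, y2, k):
    """Direct loop over the defining summation (oracle)."""
    T = len(y1)
    m1 = sum(y1) / T
    m2 = sum(y2) / T
    if k >= 0:
        return sum((y1[t] - m1) * (y2[t + k] - m2) for t in range(T - k)) / T
    return sum((y2[t] - m2) * (y1[t - k] - m1) for t in range(T + k)) / T


class TestDwtApproximation:
    def test_constant_is_preserved(self):
        out = dwt_approximation(np.full(4096, 3.7))
        assert np.max(np.abs(out - 3.7)) < 1e-8

    def test_high_frequency_sinusoid_is_removed(self):
        t = np.arange(2**14) / 1500.0
        sig = np.sin(2 * np.pi * 500.0 * t)
        out = dwt_approximation(sig)
        assert np.sum(out**2) < 0.01 * np.sum(sig**2)

    def test_white_noise_output_is_confined_to_approximation_band(self):
        # nominal level-8 approximation band edge is rate / 2**9; the sym8
        # filter's transition band straddles it, so the energy test uses
        # twice the nominal edge (one octave) to cover the roll-off
        rng = np.random.default_rng(0)
        rate = 1500.0
        out = dwt_approximation(rng.standard_normal(2**15))
        f, p = periodogram(out, fs=rate)
        assert p[f <= rate / 2**9].sum() >= 0.85 * p.sum()
        assert p[f <= rate / 2**8].sum() >= 0.95 * p.sum()

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(8192)
        once = dwt_approximation(x)
        twice = dwt_approximation(once)
        assert np.max(np.abs(twice - once)) <= 1e-6 * max(1.0, np.max(np.abs(once)))

    def test_unknown_wavelet_rejected(self):
        with pytest.raises(ValueError):
            dwt_approximation(np.zeros(4096), wavelet_name="nosuchwavelet")

    def test_short_signal_warns(self):
        with pytest.warns(UserWarning):
            dwt_approximation(np.arange(100.0), level=8)


class TestCrossCovariance:
    def test_zero_lag_is_population_variance(self):
        y = np.array([1.0, 4.0, 2.0, 8.0])
        assert cross_covariance(y, y, 0) == pytest.approx(np.var(y))

    def test_sign_flip(self):
        y = np.array([1.0, 4.0, 2.0, 8.0])
        assert cross_covariance(y, -y, 0) == pytest.approx(-np.var(y))

    def test_printed_example_against_loop_oracle(self):
        y1 = [1.0, 2.0, 3.0, 4.0]
        y2 = [0.0, 1.0, 2.0, 3.0]
        expect = brute_cross_covariance(y1, y2, 1)
        assert expect == pytest.approx(0.3125)
        assert cross_covariance(y1, y2, 1) == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("k", [-5, -1, 0, 2, 7])
    def test_random_instances_match_loop_oracle(self, k, rng):
        y1 = rng.normal(size=50)
        y2 = rng.normal(size=50)
        assert cross_covariance(y1, y2, k) == pytest.approx(
            brute_cross_covariance(list(y1), list(y2), k), abs=1e-12
        )

    def test_out_of_range_lag_rejected(self):
        with pytest.raises(LagRangeError):
            cross_covariance(np.arange(5.0), np.arange(5.0), 5)


class TestCrossCorrelation:
    def test_self_correlation_is_exactly_one(self, rng):
        y = rng.normal(size=40)
        assert cross_correlation(y, y, 0) == 1.0

    def test_negated_copy_gives_minus_one(self, rng):
        y = rng.normal(size=40)
        assert cross_correlation(y, -y, 0) == pytest.approx(-1.0, abs=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSignalError):
            cross_correlation(np.ones(10), np.arange(10.0), 0)

    @given(
        hnp.arrays(np.float64, 30, elements=st.floats(-100, 100)),
        hnp.arrays(np.float64, 30, elements=st.floats(-100, 100)),
        st.integers(-10, 10),
    )
    def test_bounded_by_one_in_magnitude(self, y1, y2, k):
        if np.ptp(y1) == 0 or np.ptp(y2) == 0:
            return
        assert abs(cross_correlation(y1, y2, k)) <= 1.0 + 1e-9

    def test_matches_brute_force_at_lag_three(self, rng):
        y1 = rng.normal(size=64)
        y2 = rng.normal(size=64)
        c = brute_cross_covariance(list(y1), list(y2), 3)
        s1 = np.sqrt(brute_cross_covariance(list(y1), list(y1), 0))
        s2 = np.sqrt(brute_cross_covariance(list(y2), list(y2), 0))
        assert cross_correlation(y1, y2, 3) == pytest.approx(c / (s1 * s2), abs=1e-12)


class TestLagEstimation:
    def test_exhaustive_noiseless_shifts_recovered_exactly(self, rng):
        base = rng.normal(size=200)
        for k in range(0, 99):
            target = np.zeros(200)
            target[k:] = base[: 200 - k]  # target delayed by k
            lag, cc = estimate_lag(base, target, k_max=99)
            assert lag == k

    def test_identical_series_gives_zero_lag_unit_cc(self, rng):
        y = rng.normal(size=300)
        lag, cc = estimate_lag(y, y, k_max=50)
        assert lag == 0 and cc == pytest.approx(1.0)

    def test_k_max_out_of_range_rejected(self, rng):
        with pytest.raises(LagRangeError):
            estimate_lag(rng.normal(size=100), rng.normal(size=100), k_max=50)


class TestApplyLag:
    def test_zero_lag_is_identity(self, rng):
        y = rng.normal(size=10)
        assert np.array_equal(apply_lag(y, 0), y)

    def test_finite_support_shift_preserves_length(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = apply_lag(y, 2)
        assert np.array_equal(out, [0.0, 0.0, 1.0, 2.0, 3.0])

    def test_alignment_fixed_point(self, rng):
        base = np.sin(np.linspace(0, 8 * np.pi, 400)) + 0.1 * rng.normal(size=400)
        target = np.zeros(400)
        target[37:] = base[: 400 - 37]
        lag, _ = estimate_lag(base, target, k_max=100)
        aligned = apply_lag(base, lag)
        residual, _ = estimate_lag(aligned, target, k_max=100)
        assert residual == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(LagRangeError):
            apply_lag(np.zeros(5), 5)


class TestLagProfile:
    def test_json_round_trip(self):
        p = LagProfile(
            channels=("VM", "TA"),
            lags=np.array([12, 30]),
            cc_at_lag=np.array([0.9, 0.8]),
            cc_at_zero=np.array([0.7, 0.6]),
        )
        q = LagProfile.from_json(p.to_json())
        assert q.channels == p.channels
        assert np.array_equal(q.lags, p.lags)

    def test_argmax_property_enforced(self):
        with pytest.raises(ValueError):
            LagProfile(
                channels=("VM",),
                lags=np.array([5]),
                cc_at_lag=np.array([0.5]),
                cc_at_zero=np.array([0.9]),
            )


def _cs(subject, load, n_cycles, n_points=100, n_ch=5, seed=0):
    rng = np.random.default_rng(seed)
    return CycleSet(
        subject_id=subject,
        load=load,
        features_raw=rng.normal(size=(n_ch, n_cycles * n_points)),
        targets=rng.normal(size=(2, n_cycles * n_points)),
        cycle_boundaries=list(range(0, n_cycles * n_points, n_points)),
        n_points=n_points,
    )


class TestDesignMatrix:
    def test_single_subject_single_cycle(self):
        f, t = assemble_design_matrix([_cs("S01", "none", 1)])
        assert f.shape == (5, 100)
        assert t.shape == (2, 100)

    def test_column_counts_always_agree(self):
        sets = [_cs("S02", "none", 3), _cs("S01", "60", 2)]
        f, t = assemble_design_matrix(sets)
        assert f.shape[1] == t.shape[1] == 500

    def test_subject_order_is_deterministic(self):
        a = _cs("S02", "none", 1, seed=1)
        b = _cs("S01", "none", 1, seed=2)
        f1, _ = assemble_design_matrix([a, b])
        f2, _ = assemble_design_matrix([b, a])
        assert np.array_equal(f1, f2)

    def test_inconsistent_shapes_rejected(self):
        with pytest.raises(ValueError):
            assemble_design_matrix(
                [_cs("S01", "none", 1, n_points=100), _cs("S02", "none", 1, n_points=50)]
            )
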