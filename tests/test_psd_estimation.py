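"""Unit tests for the Welch and Burg PSD estimators.

The Burg recursion is cross-checked against a brute-force per-stage
numerical minimizer of the summed forward+backward prediction error, and
the Welch path against scipy's independent implementation with matched
settings.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps
from scipy.optimize import minimize_scalar

from emgfatigue import (
    WelchConfig,
    burg_fit,
    burg_psd,
    modified_periodogram,
    segment_signal,
    welch_psd,
)

FS = 1024.0


# ---------------------------------------------------------------------------
# segmentation

class TestSegmentation:
    @pytest.mark.parametrize("duration_ms", range(250, 2001, 250))
    def test_thirteen_segments_at_every_study_duration(self, duration_ms):
        n = int(round(duration_ms * FS / 1000.0))
        segments = segment_signal(np.zeros(n))
        assert len(segments) == 13
        assert all(len(s) == int(round(0.25 * n)) for s in segments)

    def test_window_fraction_one_returns_whole_signal(self):
        x = np.arange(64.0)
        (seg,) = segment_signal(x, window_fraction=1.0)
        np.testing.assert_array_equal(seg, x)

    def test_zero_hop_rejected(self):
        with pytest.raises(ValueError, match="hop"):
            segment_signal(np.zeros(256), step_fraction=0.001)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            segment_signal(np.zeros(16))

    @given(n=st.integers(128, 4096))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_segment_count_arithmetic(self, n):
        """S = floor((N - M) / hop) + 1 and all segments lie inside the signal."""
        segments = segment_signal(np.zeros(n))
        m = int(round(0.25 * n))
        hop = int(round(0.25 * m))
        assert len(segments) == (n - m) // hop + 1


# ---------------------------------------------------------------------------
# modified periodogram / Welch

class TestModifiedPeriodogram:
    def test_rectangular_window_matches_scipy_periodogram(self, rng):
        x = rng.standard_normal(256)
        ours = modified_periodogram(x, np.ones(256), nfft=256, f_s=FS)
        f_ref, p_ref = sps.periodogram(x, fs=FS, window="boxcar", detrend=False)
        np.testing.assert_allclose(ours.values, p_ref, rtol=1e-10, atol=1e-15)
        np.testing.assert_allclose(ours.grid, f_ref)

    def test_parseval_consistency(self, rng):
        """Integrated one-sided PSD equals windowed-signal variance / U."""
        x = rng.standard_normal(512)
        w = sps.windows.tukey(512, 0.5)
        est = modified_periodogram(x, w, nfft=512, f_s=FS)
        integrated = est.values.sum() * est.df
        expected = np.mean((w * x) ** 2) / np.mean(w**2)
        assert integrated == pytest.approx(expected, rel=1e-6)

    def test_white_noise_level_is_flat(self, rng):
        """Averaged periodograms of unit-variance noise sit at 2/f_s per Hz."""
        acc = np.zeros(129)
        reps = 1000
        for _ in range(reps):
            x = rng.standard_normal(256)
            acc += modified_periodogram(x, np.ones(256), 256, FS).values
        level = acc[1:-1] / reps  # interior lines (doubled one-sided density)
        assert np.mean(level) == pytest.approx(2.0 / FS, rel=0.05)

    def test_all_zero_window_rejected(self):
        with pytest.raises(ValueError):
            modified_periodogram(np.ones(64), np.zeros(64), 64, FS)


class TestWelch:
    def test_single_rect_segment_reduces_to_periodogram(self, rng):
        x = rng.standard_normal(256)
        config = WelchConfig(window="boxcar", window_fraction=1.0, detrend=False)
        ours = welch_psd(x, FS, config=config)
        ref = modified_periodogram(x, np.ones(256), 256, FS)
        np.testing.assert_allclose(ours.values, ref.values, rtol=1e-12)

    def test_matches_scipy_welch_with_same_settings(self, rng):
        """Independent cross-check against scipy.signal.welch."""
        x = rng.standard_normal(1024)
        ours = welch_psd(x, FS)
        m, hop = 256, 64
        f_ref, p_ref = sps.welch(
            x,
            fs=FS,
            window=sps.windows.tukey(m, 0.5),
            noverlap=m - hop,
            nfft=1024,
            detrend="constant",
        )
        np.testing.assert_allclose(ours.grid, f_ref)
        np.testing.assert_allclose(ours.values, p_ref, rtol=1e-8)

    def test_thirteen_averaged_periodograms_default(self, rng):
        est = welch_psd(rng.standard_normal(256), FS)
        assert est.meta["segments"] == 13
        assert len(est.grid) == 129  # zero-padded to the full signal length

    def test_nonnegative_values(self, rng):
        est = welch_psd(rng.standard_normal(512), FS)
        assert np.all(est.values >= 0)

    def test_variance_reduction_vs_single_periodogram(self):
        """Averaging segments shrinks the estimate variance at a fixed line."""
        line = 40
        welch_vals, perio_vals = [], []
        for i in range(500):
            x = np.random.default_rng(i).standard_normal(512)
            welch_vals.append(welch_psd(x, FS).values[line])
            perio_vals.append(
                modified_periodogram(x, np.ones(512), 512, FS).values[line]
            )
        assert np.var(welch_vals) < np.var(perio_vals)


# ---------------------------------------------------------------------------
# Burg

def _brute_force_burg(x: np.ndarray, order: int):
    """Stage-wise numerical minimizer of the summed fwd+bwd squared error.

    Independent oracle: at each stage the reflection coefficient is found
    by scalar optimization of the lattice error instead of the closed form.
    """
    fwd = x.astype(float).copy()
    bwd = fwd.copy()
    a = np.array([1.0])
    for _ in range(order):
        f1, b1 = fwd[1:], bwd[:-1]

        def stage_error(k):
            return np.sum((f1 + k * b1) ** 2 + (b1 + k * f1) ** 2)

        res = minimize_scalar(stage_error, bounds=(-1.0, 1.0), method="bounded",
                              options={"xatol": 1e-12})
        k = res.x
        a = np.concatenate([a, [0.0]])
        a = a + k * a[::-1]
        fwd, bwd = f1 + k * b1, b1 + k * f1
    return a


class TestBurg:
    def test_ar1_parameter_recovery(self):
        rng = np.random.default_rng(7)
        e = rng.standard_normal(4296)
        x = sps.lfilter([1.0], [1.0, -0.9], e)[200:]
        model = burg_fit(x, 1)
        assert model.prediction_coefficients[0] == pytest.approx(-0.9, abs=0.02)

    def test_stage_one_closed_form(self, rng):
        """k_1 = -2 sum(x_n x_{n-1}) / sum(x_n^2 + x_{n-1}^2), edge-corrected."""
        x = rng.standard_normal(128)
        model = burg_fit(x, 1)
        expected = -2 * np.dot(x[1:], x[:-1]) / (
            np.dot(x[1:], x[1:]) + np.dot(x[:-1], x[:-1])
        )
        assert model.reflection_coefficients[0] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n,order", [(16, 1), (32, 2), (64, 4)])
    def test_matches_brute_force_minimizer(self, n, order):
        """Each stage's closed form agrees with direct numerical minimization."""
        x = np.random.default_rng(100 + n).standard_normal(n)
        model = burg_fit(x, order)
        oracle = _brute_force_burg(x, order)
        np.testing.assert_allclose(
            model.polynomial, oracle, rtol=0, atol=1e-6
        )

    @given(seed=st.integers(0, 10_000), order=st.integers(1, 12))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_stability_and_monotone_error(self, seed, order):
        """|reflection| < 1 at every stage; error power never increases."""
        x = np.random.default_rng(seed).standard_normal(96)
        model = burg_fit(x, order)
        assert np.all(np.abs(model.reflection_coefficients) < 1.0)
        assert np.all(np.diff(model.error_path) <= 1e-12)
        assert model.error_variance > 0

    def test_constant_signal_flagged(self):
        with pytest.raises(ValueError, match="constant|degenerate"):
            burg_fit(np.ones(64), 2)

    def test_order_bounds(self, rng):
        x = rng.standard_normal(32)
        with pytest.raises(ValueError):
            burg_fit(x, 0)
        with pytest.raises(ValueError):
            burg_fit(x, 32)


class TestBurgPsd:
    def test_white_noise_spectrum_is_flat(self):
        x = np.random.default_rng(3).standard_normal(4096)
        model = burg_fit(x, 3)
        est = burg_psd(model, FS, nfft=4096)
        interior = est.values[1:-1]
        assert interior.max() / interior.min() < 3.0

    def test_power_conservation(self, spec, shaping):
        from emgfatigue import generate_clean

        x = generate_clean(2000.0, spec, seed=55, shaping=shaping).samples
        model = burg_fit(x, 10)
        est = burg_psd(model, FS, nfft=len(x))
        assert est.total_power() == pytest.approx(np.mean(x**2), rel=0.05)

    @pytest.mark.parametrize("order", [3, 4, 7, 10, 15, 30])
    def test_study_orders_accepted(self, order, spec, shaping):
        from emgfatigue import generate_clean

        x = generate_clean(250.0, spec, seed=8, shaping=shaping).samples
        est = burg_psd(burg_fit(x, order), FS, nfft=len(x))
        assert np.all(est.values >= 0)
        assert est.method == f"burg{order}"

    def test_grid_parity_with_welch(self, rng):
        """Both estimators share length and spacing of the frequency grid."""
        x = rng.standard_normal(1024)
        w = welch_psd(x, FS)
        b = burg_psd(burg_fit(x, 7), FS, nfft=1024)
        np.testing.assert_array_equal(w.grid, b.grid)
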