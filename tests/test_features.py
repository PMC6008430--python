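import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from catransient.features import (
    build_feature_table,
    compute_amplitudes,
    compute_area,
    compute_delta,
    compute_derivative_extrema,
    compute_durations,
    peak_variables,
)
from catransient.peaks import Peak, annotate_signal
from catransient.signal_io import FEATURE_COLUMNS, Signal


class TestAmplitudesAndDurations:
    def test_amplitudes_direct_formula(self):
        s = np.array([1.0, 1.5, 2.0, 1.6, 1.2])
        A_l, A_r = compute_amplitudes(s, 0, 2, 4)
        assert A_l == pytest.approx(1.0)
        assert A_r == pytest.approx(0.8)

    def test_symmetric_peak_equal_sides(self):
        s = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        A_l, A_r = compute_amplitudes(s, 0, 2, 4)
        assert A_l == A_r

    def test_durations_index_arithmetic(self):
        D_l, D_r = compute_durations(0, 10, 30, fs=10.0)
        assert D_l == pytest.approx(1.0)
        assert D_r == pytest.approx(2.0)

    def test_degenerate_zero_left_duration(self):
        D_l, _ = compute_durations(5, 5, 10, fs=10.0)
        assert D_l == 0.0


class TestDelta:
    def test_top_to_top_intervals(self):
        np.testing.assert_allclose(
            compute_delta(np.array([10, 30, 60]), fs=10.0), [1.0, 2.0, 3.0]
        )

    def test_first_peak_measured_from_signal_start(self):
        np.testing.assert_allclose(compute_delta(np.array([25]), fs=10.0), [2.5])

    def test_equal_spacing_constant_from_second_peak(self):
        d = compute_delta(np.array([7, 17, 27, 37]), fs=10.0)
        assert np.allclose(d[1:], 1.0)


class TestDerivativeExtrema:
    def test_sampled_sine_matches_closed_form(self):
        # s = sin(2*pi*t) at 100 Hz; rising inflection slope 2*pi, falling
        # -2*pi, second-derivative extrema +/- 4*pi^2 on the falling side
        fs = 100.0
        t = np.arange(-0.10, 0.801 + 1e-9, 1 / fs)
        s = np.sin(2 * np.pi * t)
        a, c, g = 0, int(round(0.35 * fs)), len(t) - 1  # t=-0.1, 0.25, 0.80
        max_d1, abs_min_d1, max_d2, abs_min_d2, b, e, d, f = (
            compute_derivative_extrema(s, a, c, g, fs)
        )
        assert max_d1 == pytest.approx(2 * np.pi, rel=0.01)
        assert abs_min_d1 == pytest.approx(2 * np.pi, rel=0.01)
        assert max_d2 == pytest.approx(4 * np.pi**2, rel=0.01)
        assert abs_min_d2 == pytest.approx(4 * np.pi**2, rel=0.01)
        # landmarks: b at t=0, e at t=0.5, d at t=0.25 (s'' min), f at t=0.75
        assert t[b] == pytest.approx(0.0, abs=0.011)
        assert t[e] == pytest.approx(0.5, abs=0.011)
        assert t[d] == pytest.approx(0.25, abs=0.011)
        assert t[f] == pytest.approx(0.75, abs=0.011)

    def test_linear_rise_constant_slope(self):
        fs = 10.0
        s = np.concatenate([np.arange(6.0) * 3.0, 15.0 - np.arange(1, 6.0) * 2.0])
        max_d1, abs_min_d1, *_ = compute_derivative_extrema(s, 0, 5, 10, fs)
        assert max_d1 == pytest.approx(30.0)  # 3 units/sample * 10 Hz
        assert abs_min_d1 == pytest.approx(20.0)

    def test_absolute_values_nonnegative(self):
        s = np.array([0.0, 1.0, 3.0, 4.0, 3.0, 1.0, 0.5, 0.0])
        _, abs_min_d1, _, abs_min_d2, *_ = compute_derivative_extrema(s, 0, 3, 7, 1.0)
        assert abs_min_d1 >= 0 and abs_min_d2 >= 0

    def test_short_side_raises(self):
        s = np.array([0.0, 1.0, 0.0, 0.5, 0.2])
        with pytest.raises(ValueError, match="side"):
            compute_derivative_extrema(s, 0, 1, 4, 1.0)


class TestArea:
    def test_triangle_exact(self, triangle_signal):
        # h = 2, w = 1 s -> R = 1.0; baseline offset must not matter
        R = compute_area(triangle_signal.samples, 10, 15, 20, fs=10.0)
        assert R == pytest.approx(1.0)

    def test_gaussian_against_dense_quadrature(self):
        from scipy.integrate import quad

        fs, sig, h = 23.0, 0.3, 5.0
        t = np.arange(-1.0, 1.0 + 1e-9, 1 / fs)
        s = h * np.exp(-0.5 * (t / sig) ** 2)
        R = compute_area(s, 0, len(t) // 2, len(t) - 1, fs)
        curve, _ = quad(lambda u: h * np.exp(-0.5 * (u / sig) ** 2), t[0], t[-1])
        chord = (t[-1] - t[0]) * (s[0] + s[-1]) / 2.0
        assert R == pytest.approx(curve - chord, rel=0.005)

    def test_flat_segment_zero(self):
        assert compute_area(np.full(10, 3.3), 0, 4, 9, 10.0) == pytest.approx(0.0)

    def test_below_chord_negative(self):
        s = np.array([2.0, 1.0, 1.2, 0.8, 2.0])  # notch below the chord
        assert compute_area(s, 0, 2, 4, 1.0) < 0

    def test_strict_mode_matches_chord_when_ends_equal(self, triangle_signal):
        x = triangle_signal.samples - 5.0  # s(a) = s(g) = 0
        assert compute_area(x, 10, 15, 20, 10.0, mode="strict") == pytest.approx(
            compute_area(x, 10, 15, 20, 10.0, mode="chord")
        )

    def test_strict_mode_keeps_printed_normalization(self):
        # when s(a) != s(g) the strict form subtracts only the s(g) term
        s = np.array([1.0, 3.0, 5.0, 4.0, 2.0])
        strict = compute_area(s, 0, 2, 4, 1.0, mode="strict")
        chord = compute_area(s, 0, 2, 4, 1.0, mode="chord")
        # the two differ by exactly the omitted chord term (g-a)*s(a)/(2F)
        assert strict - chord == pytest.approx(4 * s[0] / 2.0)


class TestInvariances:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(min_value=-1e3, max_value=1e3))
    def test_baseline_offset_invariance(self, offset):
        x = np.zeros(31)
        x[10:16] = np.linspace(0.0, 2.0, 6)
        x[15:21] = np.linspace(2.0, 0.0, 6)
        sig0 = Signal("t", x, fs=10.0)
        sig1 = Signal("t", x + offset, fs=10.0)
        p = [Peak(10, 15, 20)]
        v0, v1 = peak_variables(sig0, p)[0], peak_variables(sig1, p)[0]
        for name in FEATURE_COLUMNS:
            assert getattr(v0, name) == pytest.approx(
                getattr(v1, name), rel=1e-9, abs=1e-9
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_amplitude_scaling(self, k):
        x = np.zeros(31)
        x[10:16] = np.linspace(0.0, 2.0, 6)
        x[15:21] = np.linspace(2.0, 0.0, 6)
        p = [Peak(10, 15, 20)]
        v0 = peak_variables(Signal("t", x, fs=10.0), p)[0]
        v1 = peak_variables(Signal("t", k * x, fs=10.0), p)[0]
        for name in ("A_l", "A_r", "max_d1", "abs_min_d1", "max_d2",
                     "abs_min_d2", "R"):
            assert getattr(v1, name) == pytest.approx(k * getattr(v0, name), rel=1e-9)
        for name in ("D_l", "D_r", "delta"):
            assert getattr(v1, name) == getattr(v0, name)


class TestFeatureTable:
    def test_identical_peaks_mean_equals_single(self):
        x = np.zeros(100) + 4.0
        for start in (10, 40, 70):
            x[start : start + 6] += np.linspace(0.0, 2.0, 6)
            x[start + 6 : start + 11] += np.linspace(2.0, 0.0, 6)[1:]
        sig = Signal("s", x, fs=10.0, label="WT")
        ann = annotate_signal(sig)
        assert len(ann.peaks) == 3
        mean_tab = build_feature_table([sig], [ann], aggregation="mean")
        peak_tab = build_feature_table([sig], [ann], aggregation="per_peak")
        assert len(mean_tab) == 1 and len(peak_tab) == 3
        for name in ("A_l", "A_r", "D_l", "D_r", "R"):
            assert mean_tab[name].iloc[0] == pytest.approx(
                peak_tab[name].iloc[0], rel=1e-6
            )

    def test_mean_sd_adds_sd_columns(self, small_dataset):
        signals, _ = small_dataset
        anns = [annotate_signal(s) for s in signals]
        tab = build_feature_table(signals, anns, aggregation="mean_sd")
        assert all(f"{c}_sd" in tab.columns for c in FEATURE_COLUMNS)

    def test_signal_without_peaks_excluded(self, caplog):
        flat = Signal("flat", np.full(50, 2.0), fs=10.0, label="WT")
        ann = annotate_signal(flat)
        tab = build_feature_table([flat], [ann])
        assert len(tab) == 0

    def test_unknown_aggregation_raises(self):
        with pytest.raises(ValueError, match="aggregation"):
            build_feature_table([], [], aggregation="median")
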