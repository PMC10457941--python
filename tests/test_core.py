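"""Numerical primitives: filtering, differentiation, rigid-body transform,
resampling, resultants, saturation and trigger windowing."""

import numpy as np
import pytest
import sympy
from hypothesis import given, strategies as st
from scipy.signal import butter, sosfreqz

from impactkin import (
    G,
    butterworth_lowpass,
    detect_saturation,
    five_point_stencil,
    peak_resultant,
    resample_to_grid,
    resultant,
    transform_accel_to_point,
    trigger_window,
)
from impactkin.exceptions import InvalidInputError, InvalidParameterError
from tests.conftest import make_ts


def tri(x):
    """Replicate a scalar signal on all three axes."""
    x = np.asarray(x, dtype=float)
    return np.column_stack([x, x, x])


class TestButterworthLowpass:
    def test_dc_gain_is_unity(self):
        ts = make_ts(np.full((200, 3), 5.0))
        out = butterworth_lowpass(ts, 160.0)
        np.testing.assert_allclose(out.data, 5.0, rtol=1e-9)

    def test_stopband_attenuation_matches_frequency_response(self):
        # 400 Hz tone at 1 kHz with a 160 Hz cutoff: the zero-phase gain is
        # |H|^2; evaluate it independently from the filter design.
        t = np.arange(2000) / 1000.0
        ts = make_ts(tri(np.sin(2 * np.pi * 400 * t)))
        out = butterworth_lowpass(ts, 160.0)
        sos = butter(4, 160.0 / 500.0, output="sos")
        _, h = sosfreqz(sos, worN=[400.0], fs=1000.0)
        expected_gain = np.abs(h[0]) ** 2
        measured = np.abs(out.data[500:-500, 0]).max()
        assert measured < 0.05
        assert measured == pytest.approx(expected_gain, rel=0.05)

    def test_zero_phase_preserves_pulse_peak_time(self):
        t = np.arange(300) / 1000.0
        T = 0.03
        pulse = np.where((t >= 0.1) & (t <= 0.1 + T),
                         np.sin(np.pi * (t - 0.1) / T) ** 2, 0.0)
        ts = make_ts(tri(pulse))
        out = butterworth_lowpass(ts, 160.0)
        assert abs(int(np.argmax(out.data[:, 0])) - int(np.argmax(pulse))) <= 1

    def test_double_filtering_never_amplifies(self):
        rng = np.random.default_rng(7)
        sig = rng.normal(size=(400, 3))
        # taper so the finite-window energy is well contained
        sig *= np.hanning(400)[:, None]
        once = butterworth_lowpass(make_ts(sig), 160.0)
        twice = butterworth_lowpass(once, 160.0)
        m1 = np.abs(np.fft.rfft(once.data, axis=0))
        m2 = np.abs(np.fft.rfft(twice.data, axis=0))
        # exact for an LTI filter; the reflective edge padding of the
        # zero-phase pass leaks ~1e-3 relative, hence the 1% headroom
        assert np.all(m2 <= m1 + 1e-2 * m1.max())

    def test_cutoff_at_or_above_nyquist_rejected(self):
        ts = make_ts(np.zeros((50, 3)))
        with pytest.raises(InvalidParameterError):
            butterworth_lowpass(ts, 500.0)


class TestFivePointStencil:
    def test_constant_has_zero_derivative(self):
        out = five_point_stencil(make_ts(np.full((20, 3), 3.3)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_exact_on_quadratic(self):
        t = np.arange(5.0)
        out = five_point_stencil(make_ts(tri(t ** 2), rate=1.0))
        assert out.data[2, 0] == pytest.approx(4.0, abs=1e-12)

    @given(st.lists(st.floats(-5, 5), min_size=5, max_size=5))
    def test_exact_on_degree_four_polynomials(self, coeffs):
        # the central stencil is exact (to round-off) for degree <= 4
        t = np.linspace(0.0, 1.0, 21)
        p = np.polynomial.Polynomial(coeffs)
        out = five_point_stencil(make_ts(tri(p(t)), rate=20.0))
        expected = p.deriv()(t[2:-2])
        scale = max(1.0, np.abs(expected).max())
        np.testing.assert_allclose(out.data[2:-2, 0], expected, atol=1e-8 * scale)

    def test_sine_derivative_within_symbolic_error_bound(self):
        # tolerance derived from the stencil truncation term h^4 f^(5) / 30,
        # with the fifth derivative obtained symbolically
        f0, rate = 20.0, 1000.0
        ts_sym = sympy.symbols("t")
        f_sym = sympy.sin(2 * sympy.pi * f0 * ts_sym)
        d1 = sympy.lambdify(ts_sym, sympy.diff(f_sym, ts_sym))
        d5max = float(sympy.Abs(2 * sympy.pi * f0) ** 5)
        bound = (1.0 / rate) ** 4 * d5max / 30.0

        t = np.arange(200) / rate
        out = five_point_stencil(make_ts(tri(np.sin(2 * np.pi * f0 * t)), rate=rate))
        err = np.abs(out.data[2:-2, 0] - d1(t[2:-2]))
        assert err.max() < bound * 1.01

    def test_units_follow_differentiation(self):
        out = five_point_stencil(make_ts(np.zeros((6, 3)), units="rad/s"))
        assert out.units == "rad/s^2"

    def test_short_input_rejected(self):
        with pytest.raises(InvalidInputError):
            five_point_stencil(make_ts(np.zeros((4, 3))))


class TestRigidBodyTransform:
    def test_pure_translation_is_identity(self):
        a = make_ts(np.random.default_rng(0).normal(size=(10, 3)))
        zero = make_ts(np.zeros((10, 3)), units="rad/s")
        za = make_ts(np.zeros((10, 3)), units="rad/s^2")
        out = transform_accel_to_point(a, zero, za, [0.05, -0.02, 0.1])
        np.testing.assert_allclose(out.data, a.data)

    def test_centripetal_term(self):
        # omega = 10 rad/s about z, r = 0.1 m along x: a = -omega^2 r x_hat
        n = 6
        a = make_ts(np.zeros((n, 3)))
        w = make_ts(np.tile([0.0, 0.0, 10.0], (n, 1)), units="rad/s")
        al = make_ts(np.zeros((n, 3)), units="rad/s^2")
        out = transform_accel_to_point(a, w, al, [0.1, 0.0, 0.0])
        np.testing.assert_allclose(out.data, np.tile([-10.0, 0.0, 0.0], (n, 1)), atol=1e-12)

    def test_r_parallel_to_omega_vanishes(self):
        n = 6
        a = make_ts(np.zeros((n, 3)))
        w = make_ts(np.tile([0.0, 0.0, 10.0], (n, 1)), units="rad/s")
        al = make_ts(np.zeros((n, 3)), units="rad/s^2")
        out = transform_accel_to_point(a, w, al, [0.0, 0.0, 0.1])
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_round_trip_with_negated_displacement(self):
        rng = np.random.default_rng(3)
        a = make_ts(rng.normal(size=(20, 3)))
        w = make_ts(rng.normal(size=(20, 3)), units="rad/s")
        al = make_ts(rng.normal(size=(20, 3)), units="rad/s^2")
        r = np.array([0.03, -0.05, 0.08])
        there = transform_accel_to_point(a, w, al, r)
        back = transform_accel_to_point(there, w, al, -r)
        np.testing.assert_allclose(back.data, a.data, atol=1e-12)

    def test_length_mismatch_rejected(self):
        a = make_ts(np.zeros((5, 3)))
        w = make_ts(np.zeros((6, 3)), units="rad/s")
        al = make_ts(np.zeros((5, 3)), units="rad/s^2")
        with pytest.raises(InvalidInputError):
            transform_accel_to_point(a, w, al, [0, 0, 0.1])


class TestResample:
    def test_linear_signal_exact(self):
        t = np.arange(20) / 2000.0
        out = resample_to_grid(make_ts(tri(t), rate=2000.0), 1000.0)
        np.testing.assert_allclose(out.data[:, 0], out.times(), atol=1e-15)

    def test_constant_preserved(self):
        out = resample_to_grid(make_ts(np.full((30, 3), 2.5), rate=1666.0), 1000.0)
        np.testing.assert_allclose(out.data, 2.5)

    def test_gyro_rate_sinusoid_within_interpolation_bound(self):
        # independent oracle: linear-interpolation error is bounded by
        # h^2 max|f''| / 8 for the source step h
        t = np.arange(0, 0.5, 1 / 1666.0)
        f = 50.0
        out = resample_to_grid(make_ts(tri(np.sin(2 * np.pi * f * t)), rate=1666.0), 1000.0)
        expected = np.sin(2 * np.pi * f * out.times())
        bound = (1 / 1666.0) ** 2 * (2 * np.pi * f) ** 2 / 8.0
        assert np.abs(out.data[:, 0] - expected).max() < bound

    def test_upsampling_rejected(self):
        with pytest.raises(InvalidParameterError):
            resample_to_grid(make_ts(np.zeros((10, 3))), 2000.0)


class TestResultantAndPeaks:
    @pytest.mark.parametrize(
        "sample,expected",
        [((3.0, 4.0, 0.0), 5.0), ((0.0, 0.0, 0.0), 0.0), ((1.0, 1.0, 1.0), np.sqrt(3))],
    )
    def test_resultant_values(self, sample, expected):
        assert resultant(make_ts([sample]))[0] == pytest.approx(expected)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_resultant_rotation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(8, 3))
        # random proper rotation via QR
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        np.testing.assert_allclose(
            resultant(make_ts(data @ q.T)), resultant(make_ts(data)), rtol=1e-10
        )

    def test_peak_value_and_time(self):
        ts = make_ts([[1, 0, 0], [7, 0, 0], [3, 0, 0]])
        val, t = peak_resultant(ts)
        assert (val, t) == (7.0, 0.001)

    def test_all_zero_tie_broken_earliest(self):
        assert peak_resultant(make_ts(np.zeros((10, 3)))) == (0.0, 0.0)

    def test_haversine_peak_at_half_duration(self):
        rate, T = 10000.0, 0.012
        t = np.arange(0, 0.03, 1 / rate)
        pulse = np.where(t <= T, 40.0 * np.sin(np.pi * np.clip(t / T, 0, 1)) ** 2, 0.0)
        val, tp = peak_resultant(make_ts(np.column_stack([pulse, 0 * t, 0 * t]), rate=rate))
        assert val == pytest.approx(40.0, rel=1e-6)
        assert tp == pytest.approx(T / 2, abs=1 / rate)


class TestSaturation:
    def test_gyro_sample_over_range_flagged_on_axis(self):
        ts = make_ts([[0, 0, 0], [36.0, 0, 0], [0, 0, 0]], units="rad/s")
        rep = detect_saturation(ts, 35.0)
        assert rep.flagged and rep.axes == {"x"} and list(rep.indices["x"]) == [1]

    def test_within_range_not_flagged(self):
        ts = make_ts(np.full((50, 3), 34.9), units="rad/s")
        assert not detect_saturation(ts, 35.0).flagged

    def test_boundary_counts_as_saturated(self):
        ts = make_ts([[-400.0, 0, 0]], units="g")
        assert detect_saturation(ts, 400.0).flagged


class TestTriggerWindow:
    def test_window_spans_10ms_pre_to_94ms_post(self):
        data = np.zeros((1000, 3))
        data[500, 0] = 12.0
        ev = trigger_window(make_ts(data, units="g"))
        assert ev.trigger_index == 500
        win = ev.channels["accel"]
        assert win.n == 105
        assert win.start_time == pytest.approx(0.490)
        assert win.times()[-1] == pytest.approx(0.594)
        assert ev.qc_flags == set()

    def test_subthreshold_record_gives_no_event(self):
        data = np.full((200, 3), 9.9)
        assert trigger_window(make_ts(data, units="g")) is None

    def test_early_trigger_truncates_and_flags(self):
        data = np.zeros((300, 3))
        data[4, 1] = -15.0  # negative excursions count too
        ev = trigger_window(make_ts(data, units="g"))
        assert "missing_pretrigger" in ev.qc_flags
        assert ev.channels["accel"].start_time == 0.0
        assert ev.channels["accel"].n == 99  # 4 pre + trigger + 94 post

    def test_si_input_thresholded_in_g(self):
        data = np.zeros((100, 3))
        data[50, 2] = 11.0 * G
        ev = trigger_window(make_ts(data, units="m/s^2"))
        assert ev is not None and ev.trigger_index == 50
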