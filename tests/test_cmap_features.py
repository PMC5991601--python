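"""CMAP segmentation, averaging, normalisation and the MT search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nervelocate import (
    EMGRecording,
    StimulusSeries,
    extract_amplitude_latency,
    find_motor_threshold,
    fit_linear_nerve_model,
    grand_average,
    normalize_cmaps,
    segment_by_trigger,
)
from nervelocate.errors import (
    DegenerateRange,
    IncompleteWindow,
    NoResponse,
    ShapeMismatch,
    SingularDesign,
    ThresholdNotFound,
)

FS = 2000.0


def _recording(n_samples, triggers, signal=None):
    sig = np.zeros(n_samples) if signal is None else signal
    return EMGRecording(signal=sig, sample_rate=FS,
                        trigger_times=np.asarray(triggers, dtype=float))


class TestSegmentation:
    def test_window_arithmetic(self):
        rec = _recording(4000, [0.1, 0.6, 1.1, 1.6])
        segs = segment_by_trigger(rec, 0.05)
        assert segs.shape == (4, 100)

    def test_trigger_too_close_to_end(self):
        rec = _recording(2000, [0.99])  # 10 ms of tail, 50 ms window
        with pytest.raises(IncompleteWindow):
            segment_by_trigger(rec, 0.05)

    def test_injected_template_lands_at_expected_sample(self):
        sig = np.zeros(4000)
        template = np.array([1.0, 2.0, -1.0])
        trig = [0.1, 0.6, 1.1]
        onset = int(round((0.6 + 0.007) * FS))  # 7 ms after trigger 2
        sig[onset : onset + 3] = template
        segs = segment_by_trigger(_recording(4000, trig, sig), 0.05)
        assert np.array_equal(segs[1][14:17], template)
        assert not segs[0].any() and not segs[2].any()


class TestGrandAverage:
    def test_idempotent_on_identical_segments(self):
        seg = np.sin(np.linspace(0, 3, 100))
        assert np.allclose(grand_average([seg] * 4), seg)
        assert np.allclose(grand_average([seg]), seg)

    def test_noise_suppression_rate(self):
        # averaging 4 repeats should halve the noise SD (~ sigma / sqrt(4))
        rng = np.random.default_rng(5)
        template = np.sin(np.linspace(0, 3, 4000))
        sigma = 0.3
        avg = grand_average([template + rng.normal(0, sigma, 4000)
                             for _ in range(4)])
        resid_sd = np.std(avg - template)
        assert resid_sd == pytest.approx(sigma / 2, rel=0.2)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeMismatch):
            grand_average([np.zeros(10), np.zeros(11)])

    def test_linearity(self):
        rng = np.random.default_rng(3)
        segs = rng.normal(size=(4, 50))
        assert np.allclose(grand_average(3.5 * segs), 3.5 * grand_average(segs))


class TestAmplitudeLatency:
    FS_HI = 4000.0

    def _biphasic(self, peak_s, fs):
        n = int(0.05 * fs)
        sig = np.zeros(n)
        ip = int(round(peak_s * fs))
        sig[ip] = 1.2e-3
        sig[ip + int(0.002 * fs)] = -0.8e-3
        return sig

    def test_peak_to_peak_and_latency_readback(self):
        sig = self._biphasic(7.25e-3, self.FS_HI)
        vpp, lat = extract_amplitude_latency(sig, self.FS_HI)
        assert vpp == pytest.approx(2.0e-3)
        assert lat == pytest.approx(7.25e-3)

    def test_flat_signal_no_response(self):
        with pytest.raises(NoResponse):
            extract_amplitude_latency(np.zeros(200), FS)

    def test_latency_shift_equivariance(self):
        fs = self.FS_HI
        for shift_samples in (1, 4, 13):
            a = self._biphasic(7.25e-3, fs)
            b = np.roll(a, shift_samples)
            _, lat_a = extract_amplitude_latency(a, fs)
            _, lat_b = extract_amplitude_latency(b, fs)
            assert lat_b - lat_a == pytest.approx(shift_samples / fs)


class TestNormalization:
    def test_direct_arithmetic(self):
        out = normalize_cmaps([2e-3, 4e-3, 6e-3, 8e-3])
        assert np.allclose(out, [0.0, 100 / 3, 200 / 3, 100.0])

    def test_degenerate_range(self):
        with pytest.raises(DegenerateRange):
            normalize_cmaps([5e-3, 5e-3, 5e-3, 5e-3])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(1e-4, 1e-1), min_size=4, max_size=4))
    def test_endpoints_pinned_for_any_valid_input(self, vpp):
        if vpp[3] == vpp[0]:
            return
        out = normalize_cmaps(vpp)
        assert out[0] == 0.0
        assert out[3] == pytest.approx(100.0, abs=1e-9)


class TestLinearNerveModel:
    def test_collinear_points_exact_line(self):
        levels = np.array([70e-6, 77e-6, 84e-6, 91e-6])
        ncmap = np.array([0.0, 100 / 3, 200 / 3, 100.0])
        t1, t2, r2 = fit_linear_nerve_model(levels, ncmap)
        assert t1 == pytest.approx(100.0 / 21e-6, rel=1e-9)  # 4.762 %/uA
        assert t2 == pytest.approx(-1000.0 / 3, rel=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_flat_fit(self):
        t1, t2, _ = fit_linear_nerve_model([1e-5, 2e-5, 3e-5, 4e-5],
                                           [7.0, 7.0, 7.0, 7.0])
        assert t1 == pytest.approx(0.0, abs=1e-9)
        assert t2 == pytest.approx(7.0)

    def test_exact_recovery_of_generating_line(self):
        x = np.array([1.0, 2.0, 3.5, 7.0])
        y = 3.0 * x - 10.0
        t1, t2, r2 = fit_linear_nerve_model(x, y)
        assert t1 == pytest.approx(3.0, abs=1e-9)
        assert t2 == pytest.approx(-10.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_singular_design(self):
        with pytest.raises(SingularDesign):
            fit_linear_nerve_model([5e-5] * 4, [0, 1, 2, 3])

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            x = rng.uniform(1e-5, 3e-4, size=6)
            y = rng.normal(size=6)
            X = np.column_stack([x, np.ones(6)])
            expect = np.linalg.inv(X.T @ X) @ X.T @ y  # (X'X)^-1 X'y
            t1, t2, _ = fit_linear_nerve_model(x, y)
            assert t1 == pytest.approx(expect[0], rel=1e-8)
            assert t2 == pytest.approx(expect[1], rel=1e-8)


class TestStimulusSeries:
    def test_levels_are_fixed_fractions_of_mt(self):
        s = StimulusSeries.from_mt(70e-6)
        assert np.allclose(np.array(s.levels) / s.i_mt, [1.0, 1.1, 1.2, 1.3])


class TestMotorThresholdSearch:
    @staticmethod
    def _oracle(threshold):
        return lambda i: 1.0 if i >= threshold else 0.0

    def test_returns_first_grid_value_at_or_above_threshold(self):
        res = find_motor_threshold(self._oracle(70e-6), 10e-6, 5e-6, 500e-6)
        assert res.i_mt == pytest.approx(70e-6)
        assert not res.at_floor

    def test_threshold_below_start_flags_floor(self):
        res = find_motor_threshold(self._oracle(1e-6), 10e-6, 5e-6, 500e-6)
        assert res.i_mt == pytest.approx(10e-6)
        assert res.at_floor

    def test_no_response_up_to_max(self):
        with pytest.raises(ThresholdNotFound):
            find_motor_threshold(self._oracle(1.0), 10e-6, 5e-6, 500e-6)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(1, 400), st.integers(1, 20))
    def test_grid_property_random_thresholds(self, thresh_scaled, step_scaled):
        # currents in units of 1 uA; threshold anywhere on/off the grid
        thresh = thresh_scaled * 1e-6 * 0.97
        step = step_scaled * 1e-6
        res = find_motor_threshold(self._oracle(thresh), 1e-6, step, 1e-3)
        grid = 1e-6 + np.arange(0, 1200) * step
        expected = grid[grid >= thresh - 1e-15][0]
        assert res.i_mt == pytest.approx(expected, rel=1e-9)
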