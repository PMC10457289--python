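"""Discriminator state machine, event binning and efficiency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsecount.counting_engine import (
    DiscriminatorConfig,
    bin_events,
    detection_efficiency,
    discriminate,
    discriminate_segments,
    finite_gradient,
    matched_efficiency,
    output_pulse_train,
)
from pulsecount.errors import InvalidParameterError, UndefinedEfficiencyError
from pulsecount.event_simulator import (
    AnalogTrace,
    EventStream,
    sample_poisson_events,
    synthesize_trace,
)

MINIMAL = DiscriminatorConfig(
    mode="amplitude", threshold=0.5, min_consecutive_above=1,
    min_consecutive_below=1, dead_time=0,
)


def _trace(samples, dt=8.0):
    return AnalogTrace(dt, np.asarray(samples, dtype=float))


class TestFiniteGradient:
    def test_constant_is_zero(self):
        assert np.all(finite_gradient(np.full(50, 3.0), lag=4) == 0)

    def test_ramp(self):
        m, k = 0.25, 3
        s = m * np.arange(40)
        g = finite_gradient(s, lag=k)
        np.testing.assert_allclose(g[k:], m * k)
        np.testing.assert_array_equal(g[:k], 0)

    def test_matches_brute_force(self, rng):
        s = rng.normal(size=200)
        g = finite_gradient(s, lag=3)
        expected = np.array(
            [0.0] * 3 + [s[i] - s[i - 3] for i in range(3, 200)]
        )
        np.testing.assert_allclose(g, expected)

    def test_lag_too_large(self):
        with pytest.raises(InvalidParameterError):
            finite_gradient(np.zeros(5), lag=5)


class TestDiscriminate:
    def test_single_clean_pulse(self, scint_kernel):
        ev = EventStream.monolithic([1.0], [1.0])
        tr = synthesize_trace(ev, scint_kernel, duration=10.0)
        res = discriminate(tr, MINIMAL)
        assert res.n_detected == 1
        # event recorded at the first sample crossing the threshold
        first_cross = int(np.argmax(tr.samples > 0.5))
        assert res.event_sample_indices[0] == first_cross

    def test_two_separated_pulses(self, scint_kernel):
        ev = EventStream.monolithic([1.0, 6.0], [1.0, 1.0])
        tr = synthesize_trace(ev, scint_kernel, duration=12.0)
        assert discriminate(tr, MINIMAL).n_detected == 2

    def test_record_at_end_flag(self):
        s = np.array([0.0, 0, 1, 1, 1, 0, 0, 0])
        start = discriminate(
            _trace(s), DiscriminatorConfig("amplitude", 0.5, 1, 3, 1, 0))
        end = discriminate(
            _trace(s),
            DiscriminatorConfig("amplitude", 0.5, 1, 3, 1, 0, record_at="end"))
        assert start.event_sample_indices[0] == 2
        assert end.event_sample_indices[0] == 4

    def test_consecutive_above_suppresses_single_sample_spike(self):
        s = np.zeros(40)
        s[10] = 1.0  # one-sample noise spike
        s[20:26] = 1.0  # genuine pulse
        cfg = DiscriminatorConfig("amplitude", 0.5, 1, 2, 2, 0)
        res = discriminate(_trace(s), cfg)
        assert res.n_detected == 1
        assert res.event_sample_indices[0] == 20

    def test_quantized_threshold_out_of_range_warns(self):
        from pulsecount.event_simulator import quantize_adc

        tr = quantize_adc(_trace(np.linspace(0, 1, 64)), bits=8, adc_range=1.0)
        cfg = DiscriminatorConfig("amplitude", 1e6, 1, 1, 1, 0)
        with pytest.warns(UserWarning):
            res = discriminate(tr, cfg)
        assert res.n_detected == 0


def _afterglow_fixture(n_pulses):
    """Small pulses riding a slow afterglow ramp from 0.3 to 0.5.

    The ramp pushes the absolute level toward an amplitude threshold of
    0.6, so amplitude-domain detection merges/misplaces events while the
    gradient only sees the sharp rises.
    """
    n = 1000
    s = 0.3 + 0.2 * np.arange(n) / (n - 1)
    rise = np.array([0.0, 0.13, 0.27, 0.4])
    starts = [400, 480][:n_pulses]
    for p in starts:
        s[p : p + 4] += rise
        decay = 0.4 * np.exp(-np.arange(n - p - 4) / 150.0)
        s[p + 4 :] += decay
    return _trace(s), starts


class TestGradientVsAmplitudeUnderAfterglow:
    AMP = DiscriminatorConfig("amplitude", 0.6, 1, 1, 1, 0)
    GRAD = DiscriminatorConfig("gradient", 0.2, 4, 1, 1, 0)

    def test_single_pulse_amplitude_late_gradient_on_time(self):
        tr, starts = _afterglow_fixture(1)
        amp = discriminate(tr, self.AMP)
        grad = discriminate(tr, self.GRAD)
        assert amp.n_detected == 1
        assert grad.n_detected == 1
        # gradient fires on the rising edge; amplitude waits for the
        # absolute level to clear the threshold
        assert abs(grad.event_sample_indices[0] - starts[0]) <= 4
        assert amp.event_sample_indices[0] >= grad.event_sample_indices[0]

    def test_two_pulses_amplitude_merges_gradient_resolves(self):
        tr, starts = _afterglow_fixture(2)
        amp = discriminate(tr, self.AMP)
        grad = discriminate(tr, self.GRAD)
        assert amp.n_detected == 1  # never re-arms between the pulses
        assert grad.n_detected == 2
        for got, want in zip(grad.event_sample_indices, starts):
            assert abs(got - want) <= 4

    def test_gradient_efficiency_dominates_amplitude(self):
        tr, _ = _afterglow_fixture(2)
        truth = EventStream.monolithic([1.0, 2.0], [1.0, 1.0])
        assert detection_efficiency(
            discriminate(tr, self.GRAD), truth
        ) >= detection_efficiency(discriminate(tr, self.AMP), truth)


class TestDiscriminatorProperties:
    def test_max_output_rate_one_event_per_two_samples(self):
        """Alternating above/below at minimal settings: an event every
        second sample — 62.5 MHz at the 8 ns ADC clock."""
        n_pairs = 1000
        tr = _trace(np.tile([1.0, 0.0], n_pairs))
        res = discriminate(tr, MINIMAL)
        assert res.n_detected == n_pairs
        rate_hz = res.n_detected / (len(tr.samples) * 8e-9)
        assert rate_hz == pytest.approx(62.5e6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 100.0))
    def test_amplitude_invariance(self, seed, scale):
        """Scaling a noiseless trace and threshold by k leaves events fixed."""
        rng = np.random.default_rng(seed)
        s = np.abs(rng.normal(0.5, 0.4, size=300))
        cfg = DiscriminatorConfig("amplitude", 0.7, 1, 2, 2, 3)
        a = discriminate(_trace(s), cfg)
        b = discriminate(
            _trace(s * scale),
            DiscriminatorConfig("amplitude", 0.7 * scale, 1, 2, 2, 3),
        )
        np.testing.assert_array_equal(a.event_sample_indices, b.event_sample_indices)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), dead=st.integers(0, 12))
    def test_dead_time_contract(self, seed, dead):
        """Pairwise event gaps always exceed the dead time."""
        rng = np.random.default_rng(seed)
        s = rng.normal(0.4, 0.5, size=2000)
        for mode in ("amplitude", "gradient"):
            cfg = DiscriminatorConfig(mode, 0.5, 2, 1, 1, dead)
            idx = discriminate(_trace(s), cfg).event_sample_indices
            if len(idx) > 1:
                assert np.min(np.diff(idx)) >= dead + 1


class TestBinEvents:
    def test_simple_binning(self):
        counts, dropped = bin_events([0.1, 0.9], 0.5, 2)
        np.testing.assert_array_equal(counts, [1, 1])
        assert dropped == 0

    def test_boundary_is_half_open(self):
        counts, _ = bin_events([0.5], 0.5, 2)
        np.testing.assert_array_equal(counts, [0, 1])

    def test_out_of_window_dropped_and_reported(self):
        counts, dropped = bin_events([0.1, 5.0], 0.5, 4)
        assert counts.sum() == 1
        assert dropped == 1

    def test_poisson_pixel_statistics(self):
        times = sample_poisson_events(2.0, 10_000.0, 99)
        counts, dropped = bin_events(times, 1.0, 10_000)
        ratio = counts.var(ddof=1) / counts.mean()
        assert 0.9 < ratio < 1.1
        assert counts.sum() + dropped == len(times)


class TestDetectionEfficiency:
    def test_exact_ratios(self, scint_kernel):
        truth = EventStream.monolithic([1.0, 3.0, 5.0, 7.0], np.ones(4))
        tr = synthesize_trace(truth, scint_kernel, duration=12.0)
        res = discriminate(tr, MINIMAL)
        assert detection_efficiency(res, truth) == 1.0
        fake = discriminate(
            _trace(np.zeros(100)), MINIMAL
        )  # nothing detected
        assert detection_efficiency(fake, truth) == 0.0

    def test_empty_truth_rejected(self, scint_kernel):
        tr = _trace(np.zeros(10))
        res = discriminate(tr, MINIMAL)
        with pytest.raises(UndefinedEfficiencyError):
            detection_efficiency(res, EventStream.monolithic([], []))

    def test_low_rate_gradient_near_unity(self, scint_kernel):
        """Sparse events with mild noise: essentially every electron counted."""
        effs = []
        cfg = DiscriminatorConfig("gradient", 0.2, 4, 2, 2, 2)
        for seed in range(20):
            times = sample_poisson_events(0.05, 1000.0, seed)
            if len(times) == 0:
                continue
            truth = EventStream.monolithic(times, np.ones(len(times)))
            tr = synthesize_trace(
                truth, scint_kernel, noise_sigma=0.02, duration=1000.0,
                rng_seed=seed)
            effs.append(detection_efficiency(discriminate(tr, cfg), truth))
        assert np.mean(effs) >= 0.99

    def test_matched_efficiency_diagnostic(self, scint_kernel):
        truth = EventStream.monolithic([1.0, 5.0], [1.0, 1.0])
        tr = synthesize_trace(truth, scint_kernel, duration=10.0)
        res = discriminate(tr, MINIMAL)
        assert matched_efficiency(res, truth, tolerance_us=0.5) == 1.0
        assert matched_efficiency(res, truth, tolerance_us=1e-6) <= 0.5


class TestSegmentedAndOutput:
    def test_segmented_counts_sum(self, scint_kernel):
        t1 = synthesize_trace(
            EventStream.monolithic([1.0], [1.0]), scint_kernel, duration=10.0)
        t2 = synthesize_trace(
            EventStream.monolithic([2.0, 6.0], [1.0, 1.0]), scint_kernel,
            duration=10.0)
        seg = discriminate_segments([t1, t2], MINIMAL)
        assert seg.n_detected == 3
        assert seg[0].n_detected == 1

    def test_output_pulse_train(self):
        tr = _trace(np.tile([1.0, 0.0, 0.0, 0.0], 5))
        res = discriminate(tr, MINIMAL)
        train = output_pulse_train(res, len(tr.samples), width=2)
        assert train.sum() == 2 * res.n_detected
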