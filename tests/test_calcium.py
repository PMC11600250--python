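"""Calcium-trace analysis: bleach correction, peaks, ΔF/F, alignment."""

import numpy as np
import pytest

from measort.calcium import (
    TraceRecord,
    align_traces,
    bleach_correct,
    delta_f_over_f,
    detect_calcium_spikes,
    population_summary,
)
from measort.evaluate import SpikeTrain
from measort.simulate import CalciumTrace, GroundTruth, simulate_calcium_trace


def trace_of(values, dt=0.0125):
    return CalciumTrace(np.asarray(values, dtype=float), dt)


class TestBleachCorrect:
    def test_exact_on_low_degree_polynomial(self):
        t = np.arange(2000, dtype=float)
        y = 500.0 - 0.02 * t + 1e-5 * t**2 - 1e-9 * t**3
        corrected = bleach_correct(trace_of(y), order=10)
        assert np.max(np.abs(corrected.residuals)) < 1e-6 * np.max(np.abs(y))

    def test_constant_trace_zero_residuals(self):
        corrected = bleach_correct(trace_of(np.full(100, 42.0)), order=10)
        np.testing.assert_allclose(corrected.residuals, 0.0, atol=1e-9)

    def test_reconstruction_identity_exact(self):
        rng = np.random.default_rng(0)
        y = 100 + rng.normal(0, 5, 3000)
        corrected = bleach_correct(trace_of(y), order=10)
        np.testing.assert_array_equal(corrected.residuals + corrected.fitted_baseline, y)

    def test_residual_mean_near_zero(self):
        rng = np.random.default_rng(1)
        y = 200 - 0.01 * np.arange(5000) + rng.normal(0, 3, 5000)
        corrected = bleach_correct(trace_of(y), order=10)
        assert abs(corrected.residuals.mean()) < 0.1

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            bleach_correct(trace_of(np.arange(8)), order=10)


class TestDetectCalciumSpikes:
    def test_flat_noise_below_prominence_yields_no_spikes(self):
        # white-noise peak prominences reach ~7-8 noise scales; a gate
        # safely above that must return an empty set
        rng = np.random.default_rng(2)
        corrected = bleach_correct(trace_of(100 + rng.normal(0, 1, 4000)))
        assert len(detect_calcium_spikes(corrected, prominence_mult=10.0)) == 0

    def test_single_bump_detected_at_apex(self):
        rng = np.random.default_rng(3)
        t = np.arange(2000, dtype=float)
        y = 100 + rng.normal(0, 0.5, 2000)
        y += 30 * np.exp(-((t - 700) ** 2) / (2 * 15**2))
        spikes = detect_calcium_spikes(bleach_correct(trace_of(y)))
        assert len(spikes) == 1
        assert abs(spikes.frames[0] - 700) <= 2
        assert spikes.amplitudes[0] > 0

    def test_invariance_to_added_polynomial(self):
        rng = np.random.default_rng(4)
        t = np.arange(3000, dtype=float)
        y = 100 + rng.normal(0, 0.5, 3000)
        for c in (500, 1200, 2400):
            y += 25 * np.exp(-((t - c) ** 2) / (2 * 10**2))
        poly = 50.0 - 0.05 * t + 2e-6 * t**2
        a = detect_calcium_spikes(bleach_correct(trace_of(y)))
        b = detect_calcium_spikes(bleach_correct(trace_of(y + poly)))
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_parameter_recovery_on_simulated_trace(self):
        # 20 spikes, amplitude 1, noise 1/8 of amplitude (SNR 8)
        rng = np.random.default_rng(5)
        spike_s = 5.0 + np.arange(20) * 11.5 + rng.uniform(0, 3, 20)
        assert np.diff(spike_s).min() > 2.0  # isolated events
        truth = GroundTruth((spike_s * 20000).astype(np.int64),
                            np.zeros(20, dtype=np.int64), 1)
        trace = simulate_calcium_trace(truth, frame_interval=0.0125,
                                       kernel_tau=0.4,
                                       bleach_coeffs=(80.0, -0.05, 1e-4),
                                       noise_sd=0.125, rng_seed=6,
                                       n_frames=20000)
        spikes = detect_calcium_spikes(bleach_correct(trace, order=10))
        # peak-time jitter at SNR 8: the local maximum wanders a few
        # frames along the flat top of the decay kernel, so events are
        # matched within 0.25 s (inter-event spacing is 11.5 s)
        hits = 0
        for s in spike_s:
            if np.any(np.abs(spikes.times - s) < 0.25):
                hits += 1
        assert hits >= 0.95 * 20
        assert len(spikes) - hits <= 1  # at most one false positive
        # amplitudes preserved within 10 % of the injected unit amplitude
        matched = [spikes.amplitudes[np.argmin(np.abs(spikes.times - s))]
                   for s in spike_s]
        assert np.median(matched) == pytest.approx(1.0, rel=0.1)

    def test_peak_times_within_one_frame_at_high_snr(self):
        # with negligible noise the local maximum sits on the spike frame
        spike_s = np.array([2.0, 10.0, 30.0, 55.0, 80.0])
        truth = GroundTruth((spike_s * 20000).astype(np.int64),
                            np.zeros(5, dtype=np.int64), 1)
        trace = simulate_calcium_trace(truth, frame_interval=0.0125,
                                       kernel_tau=0.4,
                                       bleach_coeffs=(80.0, -0.05),
                                       noise_sd=0.005, rng_seed=9,
                                       n_frames=8000)
        spikes = detect_calcium_spikes(bleach_correct(trace, order=10))
        assert len(spikes) == 5
        for s in spike_s:
            assert np.min(np.abs(spikes.times - s)) <= 0.0125 + 1e-9


class TestDeltaFOverF:
    def test_constant_trace_is_zero(self):
        out = delta_f_over_f(trace_of(np.full(100, 50.0)))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_five_percent_excursion(self):
        y = np.full(200, 100.0)
        y[50] = 105.0
        out = delta_f_over_f(trace_of(y))
        assert out[50] == pytest.approx(0.05)

    def test_negative_excursions_preserved(self):
        y = np.full(200, 100.0)
        y[10] = 90.0
        out = delta_f_over_f(trace_of(y), baseline_method="median")
        assert out[10] == pytest.approx(-0.1)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            delta_f_over_f(trace_of(np.linspace(-10, 1, 100)))


class TestAlignTraces:
    @staticmethod
    def calcium_set(times):
        from measort.calcium import CalciumSpikeSet

        times = np.asarray(times, dtype=float)
        return CalciumSpikeSet(frames=(times / 0.0125).astype(int), times=times,
                               amplitudes=np.ones(len(times)))

    def test_identical_times_fully_cooccur(self):
        times = np.array([1.0, 5.0, 9.0])
        table, count = align_traces(SpikeTrain(times, 10.0),
                                    self.calcium_set(times), offset=0.0)
        assert count == 3
        assert table.co_occurring.all()

    def test_known_start_delay_recovered_by_offset(self):
        ephys = np.array([2.0, 6.0, 11.0])
        table, count = align_traces(SpikeTrain(ephys, 20.0),
                                    self.calcium_set(ephys + 0.6), offset=0.6,
                                    tolerance=0.05)
        assert count == 3

    def test_disjoint_trains_do_not_cooccur(self):
        table, count = align_traces(SpikeTrain(np.array([1.0, 2.0]), 100.0),
                                    self.calcium_set([50.0, 60.0]), offset=0.0)
        assert count == 0


class TestPopulationSummary:
    @staticmethod
    def record(day, times, duration=100.0, group="control"):
        from measort.calcium import CalciumSpikeSet

        times = np.asarray(times, dtype=float)
        return TraceRecord(day=day, group=group,
                           spikes=CalciumSpikeSet(
                               frames=(times / 0.0125).astype(int),
                               times=times, amplitudes=np.ones(len(times))),
                           duration=duration)

    def test_identical_days_are_all_ones(self):
        times = np.linspace(1, 99, 50)
        records = [self.record(day, times) for day in (1, 2, 3)]
        table = population_summary(records, "control")
        np.testing.assert_allclose(table.relative_rate, 1.0)

    def test_halving_rate_cohort(self):
        rng = np.random.default_rng(6)
        records = []
        for day, n in zip((1, 2, 3, 4), (400, 200, 100, 50)):
            times = np.sort(rng.uniform(0, 100, n))
            records.append(self.record(day, times))
        table = population_summary(records, "control")
        np.testing.assert_allclose(table.relative_rate, [1, 0.5, 0.25, 0.125],
                                   rtol=0.01)

    def test_single_trace_day_reports_zero_sem(self):
        records = [self.record(1, np.linspace(1, 99, 30))]
        table = population_summary(records, "control")
        assert table.rate_sem.iloc[0] == 0.0
        assert table.n_rois.iloc[0] == 1

    def test_missing_day_one_rejected(self):
        with pytest.raises(ValueError):
            population_summary([self.record(2, [1.0, 2.0])], "control")
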