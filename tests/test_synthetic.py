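"""Rhythm, deficit, and device-sampling generator behaviour."""

import numpy as np
import pytest

from ppgtrend import (
    AFEvent,
    BeatSeries,
    DeficitModel,
    DeviceModel,
    RhythmParams,
    apply_pulse_deficit,
    compose_recording,
    derive_telemetry_hr,
    sample_device,
    simulate_af_rr,
    simulate_sinus_rr,
)
from ppgtrend.exceptions import ParameterError, ScheduleError


def _no_drift(**kw):
    return RhythmParams(hr_drift_amplitude=0.0, **kw)


class TestSinusRhythm:
    def test_zero_variance_gives_metronome(self):
        params = _no_drift(mean_hr_sinus=60.0, hrv_cv_sinus=0.0)
        beats = simulate_sinus_rr(params, 10.0, seed=42)
        np.testing.assert_allclose(beats.beat_times, np.arange(11.0))
        np.testing.assert_allclose(beats.rr_intervals, 1.0)

    def test_mean_rate_recovered_at_large_n(self):
        params = _no_drift(mean_hr_sinus=75.0, hrv_cv_sinus=0.05)
        beats = simulate_sinus_rr(params, 3600.0, seed=1)
        mean_rate = np.mean(beats.instantaneous_rate)
        assert abs(mean_rate - 75.0) / 75.0 < 0.01

    def test_zero_duration_is_empty(self, rhythm):
        assert len(simulate_sinus_rr(rhythm, 0.0, seed=0)) == 0

    def test_invalid_rate_rejected(self):
        with pytest.raises(ParameterError):
            RhythmParams(mean_hr_sinus=-5.0)


class TestAFRhythm:
    def test_zero_cv_is_regular(self):
        params = _no_drift(mean_hr_af=100.0, rr_cv_af=0.0)
        beats = simulate_af_rr(params, 60.0, seed=7)
        np.testing.assert_allclose(beats.rr_intervals, 0.6)

    def test_cv_recovered_at_large_n(self):
        beats = simulate_af_rr(RhythmParams(mean_hr_af=110.0, rr_cv_af=0.25),
                               3600.0, seed=2)
        rr = beats.rr_intervals
        cv = np.std(rr) / np.mean(rr)
        assert abs(cv - 0.25) / 0.25 < 0.15

    def test_seeding_contract(self, rhythm):
        a = simulate_af_rr(rhythm, 120.0, seed=3)
        b = simulate_af_rr(rhythm, 120.0, seed=3)
        c = simulate_af_rr(rhythm, 120.0, seed=4)
        np.testing.assert_array_equal(a.beat_times, b.beat_times)
        assert not np.array_equal(a.beat_times, c.beat_times)

    def test_rr_innovations_serially_uncorrelated(self):
        beats = simulate_af_rr(_no_drift(), 3600.0, seed=5)
        rr = beats.rr_intervals
        x, y = rr[:-1] - rr.mean(), rr[1:] - rr.mean()
        acf1 = np.sum(x * y) / np.sum((rr - rr.mean()) ** 2)
        assert abs(acf1) < 0.05


class TestComposeRecording:
    def test_empty_schedule_is_pure_sinus(self, rhythm):
        beats, events = compose_recording([], rhythm, 600.0, seed=0)
        assert events == []
        rr = beats.rr_intervals
        # sinus CV (jitter + drift) stays far below the AF CV
        assert np.std(rr) / np.mean(rr) < 0.15

    def test_full_span_event_is_pure_af(self, rhythm):
        ev = AFEvent(0.0, 3600.0, "af")
        beats, _ = compose_recording([ev], rhythm, 3600.0, seed=1)
        rr = beats.rr_intervals
        cv = np.std(rr) / np.mean(rr)
        assert abs(cv - rhythm.rr_cv_af) / rhythm.rr_cv_af < 0.2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_af_vs_sinus_variability_contrast(self, rhythm, seed):
        ev = AFEvent(600.0, 1200.0, "af")
        beats, _ = compose_recording([ev], rhythm, 1800.0, seed=seed)
        t = beats.beat_times
        rr = beats.rr_intervals
        mid = t[1:]  # interval end times
        inside = (mid > ev.onset + 2) & (mid <= ev.offset)
        outside = ~((mid > ev.onset) & (mid <= ev.offset + 2))
        cv_in = np.std(rr[inside]) / np.mean(rr[inside])
        cv_out = np.std(rr[outside]) / np.mean(rr[outside])
        assert cv_in >= 2.0 * cv_out

    def test_overlapping_events_rejected(self, rhythm):
        sched = [AFEvent(0.0, 100.0), AFEvent(50.0, 150.0)]
        with pytest.raises(ScheduleError):
            compose_recording(sched, rhythm, 200.0, seed=0)

    def test_returned_schedule_matches_input(self, rhythm):
        sched = [AFEvent(100.0, 200.0, "a"), AFEvent(300.0, 400.0, "b")]
        _, events = compose_recording(sched, rhythm, 500.0, seed=0)
        assert events == sched


class TestTelemetryRule:
    def test_metronome(self):
        beats = BeatSeries(np.arange(11.0))
        hr = derive_telemetry_hr(beats, 10.0)
        # emission starts once two beats lie strictly before the second
        np.testing.assert_array_equal(hr.time_s, np.arange(2.0, 11.0))
        np.testing.assert_allclose(hr.hr_bpm, 60.0)

    def test_hand_constructed_sequence(self):
        beats = BeatSeries(np.array([0.0, 0.5, 1.5, 2.0]))
        hr = derive_telemetry_hr(beats, 2.0)
        np.testing.assert_array_equal(hr.time_s, [1.0, 2.0])
        # at t=1 the last completed interval is 0->0.5; at t=2 it is 0.5->1.5
        np.testing.assert_allclose(hr.hr_bpm, [120.0, 60.0])

    def test_too_few_beats_gives_empty(self):
        assert len(derive_telemetry_hr(BeatSeries(np.array([1.0])), 10.0)) == 0
        assert len(derive_telemetry_hr(BeatSeries(np.empty(0)), 10.0)) == 0


class TestPulseDeficit:
    def test_full_transmission_is_identity(self):
        beats = BeatSeries(np.arange(0.0, 100.0, 0.75))
        model = DeficitModel(1.0, 1.0)
        out = apply_pulse_deficit(beats, model, seed=0)
        np.testing.assert_array_equal(out.beat_times, beats.beat_times)

    def test_transmission_monotone_in_rate(self):
        model = DeficitModel()
        rates = np.linspace(40.0, 200.0, 50)
        p = model.transmit_prob(rates)
        assert np.all(np.diff(p) <= 1e-12)
        assert np.all((p > 0) & (p <= 1))

    def test_anchor_fractions(self):
        model = DeficitModel()
        assert model.transmit_prob(80.0) == pytest.approx(0.968)
        assert model.transmit_prob(120.0) == pytest.approx(0.925)

    def test_increasing_transmission_rejected(self):
        with pytest.raises(ParameterError):
            DeficitModel(transmit_frac_at_80=0.9, transmit_frac_at_120=0.95)


class TestDeviceSampling:
    def test_fbt_noiseless_constant_rhythm(self):
        beats = BeatSeries(np.arange(0.0, 600.0, 1.0))  # 60 bpm
        model = DeviceModel.fbt(noise_sd=0.0)
        pulse = sample_device(beats, model, 600.0, seed=0)
        assert len(pulse) > 0
        np.testing.assert_allclose(pulse.pulse_bpm, 60.0)
        gaps = np.diff(pulse.time_s)
        assert gaps.min() >= 2.0 - 1e-9 and gaps.max() <= 5.0 + 1e-9

    def test_aww_gap_band(self):
        beats = BeatSeries(np.arange(0.0, 3600.0, 0.8))
        pulse = sample_device(beats, DeviceModel.aww(), 3600.0, seed=1)
        gaps = np.diff(pulse.time_s)
        assert gaps.min() >= 5.0 - 1e-9 and gaps.max() <= 6.0 + 1e-9
        assert 5.0 <= gaps.mean() <= 6.0

    def test_aws_gaps_heavy_tailed(self):
        beats = BeatSeries(np.arange(0.0, 200_000.0, 0.8))
        pulse = sample_device(beats, DeviceModel.aws(), 200_000.0, seed=2)
        gaps = np.diff(pulse.time_s)
        assert gaps.min() >= 1.0 - 1e-9 and gaps.max() <= 39.0 * 60.0 + 1e-6
        assert 250.0 <= gaps.mean() <= 600.0  # targeting ~394 s
        assert np.std(gaps) > gaps.mean()  # wildly dispersed

    def test_dropout_removes_samples(self):
        beats = BeatSeries(np.arange(0.0, 3600.0, 0.8))
        full = sample_device(beats, DeviceModel.aww(dropout_prob=0.0),
                             3600.0, seed=3)
        dropped = sample_device(beats, DeviceModel.aww(dropout_prob=0.4),
                                3600.0, seed=3)
        assert len(dropped) < 0.75 * len(full)

    def test_decorrelated_values_track_baseline_not_beats(self):
        beats = BeatSeries(np.arange(0.0, 3600.0, 0.4))  # 150 bpm
        model = DeviceModel.aww(decorrelate=True, baseline_mean=70.0)
        pulse = sample_device(beats, model, 3600.0, seed=4)
        assert abs(np.mean(pulse.pulse_bpm) - 70.0) < 3.0

    def test_gain_scales_values(self):
        beats = BeatSeries(np.arange(0.0, 600.0, 0.5))  # 120 bpm
        model = DeviceModel.aww(noise_sd=0.0, gain=0.85)
        pulse = sample_device(beats, model, 600.0, seed=5)
        np.testing.assert_allclose(pulse.pulse_bpm, 0.85 * 120.0)

    def test_empty_window_samples_omitted(self):
        # lone pair of beats at the start: later windows hold no beats
        beats = BeatSeries(np.array([0.0, 1.0]))
        pulse = sample_device(beats, DeviceModel.fbt(noise_sd=0.0),
                              600.0, seed=6)
        assert np.all(pulse.time_s <= 1.0 + 5.0)
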