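"""Simulator tests: determinism, closed-form limits, ground-truth accounting."""

import numpy as np
import pytest

from cardiobeat.errors import ParameterError
from cardiobeat.synth_signals import (
    BeatScheduleParams,
    CalciumSimParams,
    DrugResponseParams,
    McgWaveformParams,
    chronotropic_multiplier,
    generate_beat_schedule,
    render_calcium_linescan,
    render_mcg_trace,
    render_mea_recording,
    transient_template,
)


class TestBeatSchedule:
    def test_deterministic_limit_is_exact_grid(self, regular_schedule):
        beats, gt = regular_schedule
        np.testing.assert_allclose(beats, np.arange(10.0))
        assert gt.pause_indices.size == 0

    def test_same_seed_reproduces_bit_identical_schedule(self):
        p = BeatScheduleParams(base_rate=45, rate_jitter_cv=0.1, pause_rate=10,
                               duration=300, seed=42)
        b1, g1 = generate_beat_schedule(p)
        b2, g2 = generate_beat_schedule(p)
        assert np.array_equal(b1, b2)
        assert np.array_equal(g1.pause_indices, g2.pause_indices)

    def test_mean_interval_tracks_base_rate(self):
        p = BeatScheduleParams(base_rate=40, rate_jitter_cv=0.08, duration=600, seed=3)
        beats, _ = generate_beat_schedule(p)
        ibi = np.diff(beats)
        se = 0.08 * (60 / 40) / np.sqrt(ibi.size)
        assert abs(ibi.mean() - 60 / 40) < 3 * se

    def test_pause_injection_count_and_ground_truth(self):
        # ~1000 beats at 60 bpm, 50 pauses/1000 expected, each > 3 s
        p = BeatScheduleParams(base_rate=60, rate_jitter_cv=0.05, pause_rate=50,
                               pause_duration_range=(4, 5), duration=1000, seed=9)
        beats, gt = generate_beat_schedule(p)
        ibi = np.diff(beats)
        n_extreme = int(np.sum(ibi > 3.0))
        assert n_extreme == gt.pause_indices.size  # one-to-one mapping
        assert np.all(ibi[gt.pause_indices] > 3.0)
        lam = 50 * beats.size / 1000
        assert abs(n_extreme - lam) < 3 * np.sqrt(lam)

    def test_tachy_brady_alternates_between_two_exact_intervals(self):
        p = BeatScheduleParams(base_rate=60, rate_jitter_cv=0.0, pause_rate=0,
                               tachy_brady_enabled=True, tachy_brady_period=10,
                               tachy_brady_rate_ratio=2.0, duration=40)
        beats, _ = generate_beat_schedule(p)
        ibi = np.round(np.diff(beats), 9)
        assert set(ibi) == {0.5, 2.0}  # base*2 and base/2

    @pytest.mark.parametrize("kwargs", [
        dict(base_rate=0), dict(duration=-1), dict(rate_jitter_cv=-0.1),
        dict(pause_rate=5, pause_duration_range=(0.5, 6)),  # pause <= ordinary IBI
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            BeatScheduleParams(**kwargs)


class TestMcgRenderer:
    def test_zero_beats_noiseless_is_flat_zero(self):
        seg, _ = render_mcg_trace(np.empty(0), McgWaveformParams(noise_sd=0.0),
                                  duration=2.0)
        assert np.all(seg.signal == 0.0)

    def test_single_event_peak_amplitude_and_location(self):
        wf = McgWaveformParams(contraction_amplitude=100.0, noise_sd=0.0)
        seg, _ = render_mcg_trace(np.array([5.0]), wf, duration=10.0)
        i = int(np.argmax(seg.signal))
        assert seg.signal[i] == pytest.approx(100.0, abs=1e-9)
        assert abs(seg.time[i] - 5.0) <= wf.event_width / 2
        # S trough follows at the configured relative depth
        assert seg.signal.min() == pytest.approx(-20.0, rel=1e-6)

    def test_event_count_conserved(self, noisy_trace):
        seg, beats, _ = noisy_trace
        # every scheduled beat leaves a local maximum near its time
        for t0 in beats:
            m = (seg.time > t0 - 0.1) & (seg.time < t0 + 0.1)
            assert seg.signal[m].max() > 50

    def test_overlapping_events_rejected(self):
        with pytest.raises(ParameterError):
            render_mcg_trace(np.array([0.0, 0.3]), McgWaveformParams(event_width=0.5))

    def test_same_seed_bit_identical(self):
        wf = McgWaveformParams(noise_sd=2.0)
        beats = np.arange(0, 10.0)
        s1, _ = render_mcg_trace(beats, wf, seed=5, duration=11)
        s2, _ = render_mcg_trace(beats, wf, seed=5, duration=11)
        assert np.array_equal(s1.signal, s2.signal)


class TestMeaRenderer:
    def test_bad_channels_marked_and_noise_only(self):
        beats = np.arange(0, 10.0)
        seg, gt = render_mea_recording(beats, n_channels=6, n_bad_channels=2,
                                       seed=1, duration=11)
        assert gt.bad_channels.size == 2
        for ch in gt.bad_channels:
            assert np.abs(seg.signal[:, ch]).max() < 100  # no 300-uV spikes

    def test_good_channels_carry_every_beat_with_small_latency(self):
        beats = np.arange(0, 10.0)
        seg, gt = render_mea_recording(beats, n_channels=4, n_bad_channels=0,
                                       seed=2, duration=11)
        for ch in range(4):
            x = seg.signal[:, ch]
            for t0 in beats:
                m = (seg.time >= t0) & (seg.time <= t0 + 0.010)
                assert x[m].max() > 200

    def test_too_few_channels_rejected(self):
        with pytest.raises(ParameterError):
            render_mea_recording(np.arange(3.0), n_channels=2)


class TestCalciumRenderer:
    def test_noiseless_trace_is_sum_of_templates(self):
        params = CalciumSimParams(noise_sd=0.0, spark_rate=0.0)
        tps = np.array([1.0, 2.5, 4.0])
        seg, _ = render_calcium_linescan(tps, params, duration=5.0)
        expected = np.zeros_like(seg.time)
        for tp in tps:
            expected += transient_template(seg.time, tp, params)
        np.testing.assert_allclose(seg.signal, 100.0 * (1 + expected), rtol=1e-12)

    def test_exponential_decay_analytic_time_to_10pct(self):
        params = CalciumSimParams(noise_sd=0.0, spark_rate=0.0, decay_tau=0.2)
        seg, _ = render_calcium_linescan(np.array([1.0]), params, duration=4.0)
        dff = seg.signal / 100.0 - 1.0
        p = int(np.argmax(dff))
        below = np.flatnonzero(dff[p:] < 0.1 * dff[p])
        t_meas = below[0] / params.line_rate
        assert abs(t_meas - 0.2 * np.log(10)) <= 1.0 / params.line_rate

    def test_sparks_live_in_diastole_and_are_listed(self):
        params = CalciumSimParams(spark_rate=2.0, noise_sd=0.0)
        tps = np.arange(1.0, 29.0, 1.5)
        _, gt = render_calcium_linescan(tps, params, seed=8, duration=30.0)
        assert gt.spark_times.size > 0
        t_full = params.rise_time / 0.9
        for ts in gt.spark_times:
            # outside every transient's rise-to-decay span
            assert np.all(
                (ts < tps - t_full) | (ts > tps + 5 * params.decay_tau)
            )

    def test_sub_transient_spark_constraint_enforced(self):
        with pytest.raises(ParameterError):
            CalciumSimParams(spark_amplitude_fraction=1.2)

    def test_kymograph_averages_back_to_profile(self):
        params = CalciumSimParams(noise_sd=0.05, spark_rate=0.0)
        seg, _ = render_calcium_linescan(np.array([1.0]), params, seed=3,
                                         duration=3.0, n_positions=16)
        assert seg.signal.shape == (300, 16)


class TestDrugResponse:
    def test_chronotropic_multiplier_anchored_and_log_linear(self):
        drug = DrugResponseParams(chronotropy_slope=0.1)
        assert chronotropic_multiplier(drug, 1e-5) == pytest.approx(1.0)
        assert chronotropic_multiplier(drug, 1e-2) == pytest.approx(1.3)

    def test_profile_length_must_match_ladder(self):
        with pytest.raises(ParameterError):
            DrugResponseParams(concentrations=(1e-5, 1e-4),
                               inotropy_profile=(1.0,))
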