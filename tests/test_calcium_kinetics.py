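"""Calcium transient kinetics and spark detection."""

import numpy as np
import pytest

from cardiobeat.calcium_kinetics import (
    CalciumProfile,
    SparkConfig,
    detect_sparks,
    detect_transients,
    normalize_f0,
)
from cardiobeat.errors import InputError, UndefinedMetricError
from cardiobeat.synth_signals import CalciumSimParams, render_calcium_linescan
from cardiobeat.validation import recall_precision


def _profile(dff, fs=100.0):
    t = np.arange(len(dff)) / fs
    return CalciumProfile(time=t, dff=np.asarray(dff, float),
                          raw=100 * (1 + np.asarray(dff, float)),
                          line_rate=fs, f0=100.0)


class TestNormalizeF0:
    def test_constant_trace_maps_to_zero(self):
        t = np.arange(200) / 100.0
        prof = normalize_f0(np.full(200, 7.5), time=t, line_rate=100.0)
        np.testing.assert_allclose(prof.dff, 0.0, atol=1e-12)

    def test_algebraic_identity(self, rng):
        # raw = F0 * (1 + x) with min(x) = 0 -> dF/F0 recovers x exactly
        t = np.arange(500) / 100.0
        x = np.abs(rng.normal(0.5, 0.2, 500))
        x -= x.min()
        raw = 50.0 * (1 + x)
        prof = normalize_f0(raw, time=t, line_rate=100.0, percentile=0.0)
        np.testing.assert_allclose(prof.dff, x, atol=1e-12)

    def test_amplitude_recovered_from_simulation(self):
        params = CalciumSimParams(noise_sd=0.01, spark_rate=0.0,
                                  transient_amplitude=2.0)
        seg, _ = render_calcium_linescan(np.arange(1.0, 28.0, 1.5), params,
                                         seed=2, duration=30.0)
        prof = normalize_f0(seg)
        events = detect_transients(prof)
        amps = [e.peak_amplitude for e in events]
        assert np.mean(amps) == pytest.approx(2.0, rel=0.05)

    def test_nonpositive_baseline_rejected(self):
        t = np.arange(200) / 100.0
        with pytest.raises(InputError):
            normalize_f0(np.full(200, -1.0), time=t, line_rate=100.0)


class TestTransients:
    def test_time_to_peak_matches_configured_rise(self):
        params = CalciumSimParams(noise_sd=0.0, spark_rate=0.0, rise_time=0.05)
        seg, _ = render_calcium_linescan(np.array([2.0]), params, duration=4.0)
        prof = normalize_f0(seg, percentile=10.0)
        events = detect_transients(prof)
        assert len(events) == 1
        assert events[0].time_to_peak == pytest.approx(0.05, abs=1.5 / 100.0)

    @pytest.mark.parametrize("tau", [0.05, 0.1, 0.2, 0.5, 1.0])
    def test_decay_time_analytic_across_tau_range(self, tau):
        params = CalciumSimParams(noise_sd=0.0, spark_rate=0.0, decay_tau=tau)
        seg, _ = render_calcium_linescan(np.array([2.0]), params,
                                         duration=4.0 + 8 * tau)
        events = detect_transients(normalize_f0(seg))
        assert len(events) == 1
        assert events[0].decay_time == pytest.approx(tau * np.log(10),
                                                     abs=1.0 / 100.0)

    def test_flat_trace_yields_no_transients(self):
        assert detect_transients(_profile(np.zeros(300))) == []

    def test_onset_precedes_peak(self):
        params = CalciumSimParams(noise_sd=0.01, spark_rate=0.0)
        seg, _ = render_calcium_linescan(np.arange(1.0, 14.0, 1.5), params,
                                         seed=4, duration=15.0)
        for ev in detect_transients(normalize_f0(seg)):
            assert ev.onset_time < ev.peak_time
            assert ev.time_to_peak == pytest.approx(
                ev.peak_time - ev.onset_time, abs=1e-12
            )


@pytest.fixture(scope="module")
def spiked():
    params = CalciumSimParams(spark_rate=2.0, spark_amplitude_fraction=0.3,
                              noise_sd=0.02)
    tps = np.arange(1.0, 29.0, 1.5)
    seg, gt = render_calcium_linescan(tps, params, seed=5, duration=30.0)
    prof = normalize_f0(seg)
    transients = detect_transients(prof)
    sparks, rate, bins = detect_sparks(prof, transients)
    return gt, transients, sparks, rate, bins


class TestSparks:

    def test_recall_and_precision(self, spiked):
        gt, _, sparks, _, _ = spiked
        rec, prec = recall_precision(np.array([s.time for s in sparks]),
                                     gt.spark_times, tolerance=0.1)
        assert rec >= 0.9 and prec >= 0.9

    def test_sparks_disjoint_from_transients(self, spiked):
        _, transients, sparks, _, _ = spiked
        for s in sparks:
            for tr in transients:
                lo, hi = tr.span
                assert not (lo <= s.time <= hi)

    def test_null_trace_false_positive_rate(self):
        params = CalciumSimParams(spark_rate=0.0, noise_sd=0.02)
        worst = 0.0
        for seed in range(3):
            seg, _ = render_calcium_linescan(np.arange(1.0, 29.0, 1.5), params,
                                             seed=seed, duration=30.0)
            prof = normalize_f0(seg)
            _, rate, _ = detect_sparks(prof, detect_transients(prof))
            worst = max(worst, rate)
        assert worst <= 0.1

    def test_sub_threshold_sparks_invisible(self):
        # spark amplitude below k * noise SD -> zero detections
        params = CalciumSimParams(spark_rate=2.0, spark_amplitude_fraction=0.01,
                                  noise_sd=0.05)
        seg, gt = render_calcium_linescan(np.arange(1.0, 29.0, 1.5), params,
                                          seed=6, duration=30.0)
        prof = normalize_f0(seg)
        sparks, _, _ = detect_sparks(prof, detect_transients(prof),
                                     SparkConfig(noise_multiple=6.0))
        assert len(sparks) == 0

    def test_scale_invariance_of_spark_detection(self, spiked):
        params = CalciumSimParams(spark_rate=2.0, spark_amplitude_fraction=0.3,
                                  noise_sd=0.02)
        seg, _ = render_calcium_linescan(np.arange(1.0, 29.0, 1.5), params,
                                         seed=5, duration=30.0)
        prof = normalize_f0(seg)
        scaled = CalciumProfile(time=prof.time, dff=5.0 * prof.dff,
                                raw=prof.raw, line_rate=prof.line_rate,
                                f0=prof.f0)
        s1, r1, _ = detect_sparks(prof, detect_transients(prof))
        s2, r2, _ = detect_sparks(scaled, detect_transients(scaled))
        assert r1 == pytest.approx(r2)
        assert len(s1) == len(s2)

    def test_no_diastole_undefined(self):
        prof = _profile(np.zeros(200))
        from cardiobeat.calcium_kinetics import TransientEvent
        whole = TransientEvent(onset_time=0.0, peak_time=0.5,
                               peak_amplitude=1.0, time_to_peak=0.5,
                               decay_time=10.0)
        with pytest.raises(UndefinedMetricError):
            detect_sparks(prof, [whole])
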