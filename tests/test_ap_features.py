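"""Action-potential detection, features, classification and arrhythmia."""

import warnings

import numpy as np
import pytest

from cardioclamp import ap_features as ap
from cardioclamp import synthdata as sd


class TestDetection:
    def test_counts_one_segment_per_beat(self, ap_trace_clean):
        _, trace = ap_trace_clean
        assert len(ap.detect_aps(trace)) == 10

    def test_flat_trace_yields_no_segments(self):
        trace = ap.APTrace(time_s=np.arange(0, 5, 5e-5),
                           voltage_mV=np.full(100_000, -70.0),
                           sample_rate=20_000)
        assert ap.detect_aps(trace) == []

    def test_ta_hump_not_counted_as_ap(self):
        spec = sd.APWaveformSpec(rate_bpm=40.0,
                                 ta_events=[(1, 600.0, 25.0)], seed=2)
        with_ta = sd.simulate_ap_train(spec, duration_s=10.0)
        spec0 = sd.APWaveformSpec(rate_bpm=40.0, seed=2)
        without = sd.simulate_ap_train(spec0, duration_s=10.0)
        assert len(ap.detect_aps(with_ta)) == len(ap.detect_aps(without))


class TestFeatures:
    def test_roundtrip_of_generated_features(self, ap_trace_clean):
        spec, trace = ap_trace_clean
        feats = ap.compute_ap_features(trace, ap.detect_aps(trace))
        assert feats.apd50 == pytest.approx(spec.apd50_ms, abs=2.0)
        assert feats.apd90 == pytest.approx(spec.apd90_ms, abs=2.0)
        assert feats.apa == pytest.approx(spec.amplitude_mV, abs=0.5)
        assert feats.mdp == pytest.approx(spec.mdp_mV, abs=0.5)
        assert feats.vmax == pytest.approx(spec.upstroke_vmax, rel=0.05)
        assert feats.bpm == pytest.approx(spec.rate_bpm, abs=0.5)

    def test_plateau_pulse_has_equal_apds(self):
        """A trapezoidal pulse repolarizes all at once, so APD50 ~ APD90 ~
        the plateau width."""
        sr = 20_000
        t = np.arange(0, 3.0, 1 / sr)
        v = np.full_like(t, -80.0)
        for start in (0.5, 1.5):
            rise = (t >= start) & (t < start + 0.002)
            v[rise] = -80.0 + 110.0 * (t[rise] - start) / 0.002
            plateau = (t >= start + 0.002) & (t < start + 0.202)
            v[plateau] = 30.0
            fall = (t >= start + 0.202) & (t < start + 0.204)
            v[fall] = 30.0 - 110.0 * (t[fall] - start - 0.202) / 0.002
        trace = ap.APTrace(time_s=t, voltage_mV=v, sample_rate=sr)
        feats = ap.compute_ap_features(trace, ap.detect_aps(trace))
        assert feats.apd90 - feats.apd50 < 2.0
        assert feats.apd50 == pytest.approx(202.0, abs=2.5)

    def test_bpm_from_inter_ap_intervals(self):
        spec = sd.APWaveformSpec(rate_bpm=60.0, seed=3)
        trace = sd.simulate_ap_train(spec, duration_s=60.0)
        feats = ap.compute_ap_features(trace, ap.detect_aps(trace))
        assert feats.n_aps == 60
        assert feats.bpm == pytest.approx(60.0, abs=0.1)

    def test_single_ap_has_undefined_bpm(self):
        spec = sd.APWaveformSpec(rate_bpm=30.0, seed=4)
        trace = sd.simulate_ap_train(spec, duration_s=2.2)
        segs = ap.detect_aps(trace)
        assert len(segs) == 1
        with pytest.warns(UserWarning, match="BPM undefined"):
            feats = ap.compute_ap_features(trace, segs)
        assert feats.bpm is None

    def test_offset_shifts_mdp_not_apa(self, ap_trace_clean):
        _, trace = ap_trace_clean
        feats = ap.compute_ap_features(trace, ap.detect_aps(trace))
        shifted = ap.APTrace(time_s=trace.time_s,
                             voltage_mV=trace.voltage_mV + 7.0,
                             sample_rate=trace.sample_rate)
        feats2 = ap.compute_ap_features(shifted, ap.detect_aps(shifted))
        assert feats2.apa == pytest.approx(feats.apa, abs=1e-9)
        assert feats2.mdp == pytest.approx(feats.mdp + 7.0, abs=1e-9)
        assert (feats2.per_ap["apd90"] >= feats2.per_ap["apd50"]).all()


class TestSubtype:
    def _features(self, apd50, apd90, apa):
        return ap.APFeatureSet(bpm=50.0, vmax=20.0, apd50=apd50, apd90=apd90,
                               apa=apa, mdp=-72.0, apd_ratio=apd90 / apd50,
                               n_aps=10)

    def test_ventricular_like_at_reported_values(self):
        feats = self._features(209.9, 253.6, 114.8)
        assert ap.classify_subtype(feats) == "ventricular-like"

    def test_ratio_boundary_is_strict(self):
        feats = self._features(200.0, 270.0, 114.8)   # ratio exactly 1.35
        assert feats.apd_ratio == pytest.approx(1.35)
        assert ap.classify_subtype(feats) == "other"

    def test_apa_boundary_is_strict(self):
        feats = self._features(209.9, 253.6, 90.0)
        assert ap.classify_subtype(feats) == "other"


class TestTriggeredActivity:
    def test_injected_events_are_counted(self):
        spec = sd.APWaveformSpec(rate_bpm=40.0,
                                 ta_events=[(1, 600.0, 25.0), (3, 700.0, 25.0)],
                                 seed=2)
        trace = sd.simulate_ap_train(spec, duration_s=10.0)
        count, arrhythmic = ap.detect_triggered_activity(trace,
                                                         ap.detect_aps(trace))
        assert count == 2
        assert arrhythmic

    def test_clean_train_has_none(self, ap_trace_clean):
        _, trace = ap_trace_clean
        count, arrhythmic = ap.detect_triggered_activity(trace,
                                                         ap.detect_aps(trace))
        assert count == 0 and not arrhythmic

    @pytest.mark.parametrize("flagged,total,expected",
                             [(11, 41, 26.8), (6, 36, 16.7), (1, 29, 3.4),
                              (0, 17, 0.0)])
    def test_cohort_fraction_arithmetic(self, flagged, total, expected):
        flags = [True] * flagged + [False] * (total - flagged)
        assert round(ap.cohort_ta_fraction(flags), 1) == expected

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            ap.cohort_ta_fraction([])


class TestSpikeAndDome:
    def test_prominent_notch_dome_flagged(self):
        spec = sd.APWaveformSpec(rate_bpm=50.0, spike_and_dome=True,
                                 notch_depth_mV=8.0, seed=5)
        trace = sd.simulate_ap_train(spec, duration_s=6.0)
        flag, metrics = ap.detect_spike_and_dome(trace, ap.detect_aps(trace)[1])
        assert flag
        assert metrics["notch_dome_delta_mV"] == pytest.approx(8.0, abs=1.0)

    def test_monotone_repolarization_not_flagged(self, ap_trace_clean):
        _, trace = ap_trace_clean
        flag, _ = ap.detect_spike_and_dome(trace, ap.detect_aps(trace)[1])
        assert not flag

    def test_subthreshold_notch_not_flagged(self):
        spec = sd.APWaveformSpec(rate_bpm=50.0, spike_and_dome=True,
                                 notch_depth_mV=0.5, seed=5)
        trace = sd.simulate_ap_train(spec, duration_s=6.0)
        flag, _ = ap.detect_spike_and_dome(trace, ap.detect_aps(trace)[1])
        assert not flag


class TestContraction:
    def test_symmetric_triangle_halfwidths(self):
        """A triangular event of 200 ms base has 50-ms half-widths on both
        the rising and falling phases."""
        t = np.arange(0, 2.0, 1 / 60.0)
        y = np.zeros_like(t)
        rise = (t >= 0.5) & (t < 0.6)
        y[rise] = (t[rise] - 0.5) / 0.1
        fall = (t >= 0.6) & (t < 0.7)
        y[fall] = 1.0 - (t[fall] - 0.6) / 0.1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            feats = ap.contraction_halfwidths(t, y)
        assert feats.contraction_halfwidth == pytest.approx(50.0, abs=1e-6)
        assert feats.relaxation_halfwidth == pytest.approx(50.0, abs=1e-6)

    def test_roundtrip_from_ap_locked_generator(self, ap_trace_clean):
        _, trace = ap_trace_clean
        frames, y = sd.simulate_contraction_trace(trace, contraction_hw_ms=100.0,
                                                  relaxation_hw_ms=110.0)
        feats = ap.contraction_halfwidths(frames, y,
                                          sync_pulse_times_s=np.array([0.0]))
        frame_ms = 1000.0 / 60.0
        assert feats.contraction_halfwidth == pytest.approx(100.0, abs=frame_ms)
        assert feats.relaxation_halfwidth == pytest.approx(110.0, abs=frame_ms)
        assert feats.sync_offset is not None

    def test_missing_sync_pulses_warns(self):
        t = np.arange(0, 2.0, 1 / 60.0)
        y = np.exp(-0.5 * ((t - 1.0) / 0.05) ** 2)
        with pytest.warns(UserWarning, match="sync"):
            feats = ap.contraction_halfwidths(t, y)
        assert feats.sync_offset is None


class TestSpecValidation:
    def test_apd_longer_than_period_rejected(self):
        with pytest.raises(sd.SpecError, match="period"):
            sd.simulate_ap_train(sd.APWaveformSpec(rate_bpm=300.0, seed=0))

    def test_bad_apd_ordering_rejected(self):
        with pytest.raises(sd.SpecError):
            sd.APWaveformSpec(apd50_ms=300.0, apd90_ms=250.0)

    def test_ta_in_repolarization_rejected(self):
        with pytest.raises(sd.SpecError, match="diastole"):
            spec = sd.APWaveformSpec(rate_bpm=50.0,
                                     ta_events=[(0, 100.0, 25.0)], seed=0)
            sd.simulate_ap_train(spec, duration_s=5.0)
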