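"""Slow-wave detection cascade: spectrum, gates, streaming, wire format."""

import struct

import numpy as np
import pytest
from hypothesis import given, strategies as st

import biologger as bl
from biologger.detector import NoDominantFrequencyError


def buffer_of(freq, amp=150.0, phase0=0.0, fs=125.0, duration=2.0):
    return bl.make_sinusoid(freq, amp, phase0=phase0, duration=duration, fs=fs).samples


class TestEstimateSpectrum:
    @pytest.mark.parametrize("freq", [0.5, 1.5, 2.0, 3.5, 10.0])
    def test_on_grid_frequency_is_exact(self, det_config, freq):
        est = bl.estimate_spectrum(buffer_of(freq), 125, det_config)
        assert est.fc == freq

    @pytest.mark.parametrize("freq, nearest", [(1.6, 1.5), (2.6, 2.5), (3.4, 3.5)])
    def test_off_grid_frequency_snaps_to_nearest_bin(self, det_config, freq, nearest):
        est = bl.estimate_spectrum(buffer_of(freq), 125, det_config)
        assert est.fc == nearest

    @pytest.mark.parametrize("phase0", [0.0, 45.0, 123.4, 270.0, 359.0])
    def test_phase_referenced_to_last_sample(self, det_config, phase0):
        est = bl.estimate_spectrum(buffer_of(1.5, phase0=phase0), 125, det_config)
        true = (phase0 + 360.0 * 1.5 * 249 / 125) % 360.0
        err = abs((est.phase_at_fc - true + 180) % 360 - 180)
        assert err < 0.5

    @pytest.mark.parametrize("phase0", [0.0, 200.0])
    def test_tail_window_keeps_grid_and_phase(self, det_config, phase0):
        tail = buffer_of(2.5, phase0=phase0, duration=1.0)
        est = bl.estimate_spectrum(tail, 125, det_config)
        assert est.fc == 2.5  # zero-padding preserves the 0.5 Hz grid
        true = (phase0 + 360.0 * 2.5 * 124 / 125) % 360.0
        err = abs((est.phase_at_fc - true + 180) % 360 - 180)
        assert err < 0.5

    def test_fast_rhythm_has_negligible_sw_leakage(self, det_config):
        est = bl.estimate_spectrum(buffer_of(10.0, amp=100.0), 125, det_config)
        assert est.fc == 10.0
        assert est.sw_power / est.ref_power < 0.01

    def test_all_zero_window_signals_no_dominant_frequency(self, det_config):
        with pytest.raises(NoDominantFrequencyError):
            bl.estimate_spectrum(np.zeros(250), 125, det_config)

    def test_wrong_length_rejected(self, det_config):
        with pytest.raises(ValueError):
            bl.estimate_spectrum(np.ones(200), 125, det_config)


class TestSwAmplitude:
    def test_passband_tone_passes_near_unity(self, det_config):
        amp = bl.sw_amplitude(buffer_of(2.0, amp=100.0), det_config)
        assert 85 <= amp <= 105

    def test_stopband_tone_strongly_attenuated(self, det_config):
        amp = bl.sw_amplitude(buffer_of(20.0, amp=100.0), det_config)
        assert amp < 15

    def test_zero_input_gives_zero(self, det_config):
        assert bl.sw_amplitude(np.zeros(250), det_config) == 0.0


class TestDetect:
    def test_slow_wave_detected_on_full_path(self, det_config):
        res = bl.detect(buffer_of(1.5), det_config)
        assert res is not None
        assert res.fc == 1.5 and not res.used_tail

    def test_fast_slow_wave_takes_tail_path(self, det_config):
        res = bl.detect(buffer_of(3.0), det_config)
        assert res is not None
        assert res.fc == 3.0 and res.used_tail

    def test_out_of_band_rhythm_rejected_with_reason(self, det_config):
        diag = {}
        assert bl.detect(buffer_of(8.0), det_config, diagnostics=diag) is None
        assert diag["failed_gate"] == "fc_band"

    def test_small_amplitude_fails_amplitude_gate(self, det_config):
        diag = {}
        assert bl.detect(buffer_of(1.5, amp=20.0), det_config, diagnostics=diag) is None
        assert diag["failed_gate"] == "amplitude"

    def test_raising_thresholds_never_adds_detections(self, det_config):
        rng = np.random.default_rng(0)
        t = np.arange(60 * 125) / 125
        trace = bl.EEGTrace(
            100 * np.cos(2 * np.pi * 1.5 * t) + rng.normal(0, 40, t.size), 125
        )
        counts = []
        for ratio, amp in [(1.0, 40.0), (2.0, 80.0), (4.0, 120.0), (8.0, 200.0)]:
            cfg = bl.DetectorConfig(ratio_threshold=ratio, amplitude_threshold=amp)
            counts.append(len(bl.run_detector(trace, cfg)))
        assert counts == sorted(counts, reverse=True)


class TestRunDetector:
    def test_cadence_and_refractory_on_pure_tone(self, det_config):
        trace = bl.make_sinusoid(1.5, 150, duration=60, fs=125)
        dets = bl.run_detector(trace, det_config)
        assert 13 <= len(dets) <= 15
        times = [d.time for d in dets]
        assert times == sorted(times)
        assert [d.trial_number for d in dets] == list(range(len(dets)))
        # refractory: no two detections closer than 4 s
        assert np.all(np.diff(times) >= det_config.refractory_s - 1e-9)

    def test_zero_input_yields_no_detections(self, det_config):
        dets = bl.run_detector(bl.EEGTrace(np.zeros(60 * 125), 125), det_config)
        assert dets == []

    def test_detections_confined_to_nrem(self, overnight_1h):
        # thresholds set clearly above what wake broadband noise can
        # produce, per the cross-check's premise
        cfg = bl.DetectorConfig(ratio_threshold=3.0, amplitude_threshold=100.0)
        rec = overnight_1h
        dets = bl.run_detector(rec.eeg, cfg)
        assert len(dets) > 0
        for d in dets:
            idx = int(round(d.time * 125)) + 1
            # every detection's 2-s analysis buffer must contain NREM
            # slow waves; a buffer of pure wake data never triggers
            # (bout-transition buffers legitimately straddle both states)
            window = rec.state_labels[max(0, idx - 250) : idx]
            assert window.mean() > 0.1
        # and the vast majority are deep inside sleep
        in_sleep = [
            rec.state_labels[int(round(d.time * 125)) - 249 : int(round(d.time * 125)) + 1].mean() > 0.9
            for d in dets
        ]
        assert np.mean(in_sleep) > 0.9


class TestWireFormat:
    def test_round_trip_preserves_all_wire_fields(self):
        r = bl.DetectionResult(
            time=12.345, trial_number=7, fc=2.5, phase_at_fc=123.5, used_tail=True
        )
        rt = bl.deserialize_detection(bl.serialize_detection(r))
        assert (rt.time, rt.trial_number, rt.fc, rt.phase_at_fc) == (
            12.345, 7, 2.5, 123.5,
        )

    @given(
        time_ms=st.integers(0, 2**32 - 1),
        trial=st.integers(0, 2**32 - 1),
        fc=st.floats(0.5, 12.0, width=32),
        phase=st.floats(0.0, 359.989990234375, width=32),
    )
    def test_payload_is_exactly_16_bytes(self, time_ms, trial, fc, phase):
        r = bl.DetectionResult(time_ms / 1000.0, trial, fc, phase)
        assert len(bl.serialize_detection(r)) == 16

    @given(raw=st.binary(min_size=16, max_size=16))
    def test_bytes_round_trip_through_decode(self, raw):
        time_ms, trial, fc, phase = struct.unpack("<IIff", raw)
        if not (np.isfinite(fc) and np.isfinite(phase)):
            return
        assert bl.serialize_detection(bl.deserialize_detection(raw)) == raw

    @pytest.mark.parametrize("field, value", [("trial_number", 2**32), ("time", 2**32 / 1000)])
    def test_overflowing_fields_rejected(self, field, value):
        kwargs = dict(time=1.0, trial_number=1, fc=2.0, phase_at_fc=0.0)
        kwargs[field] = value
        with pytest.raises(OverflowError):
            bl.serialize_detection(bl.DetectionResult(**kwargs))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            bl.deserialize_detection(b"\x00" * 15)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(buffer_s=1.999),
            dict(sw_band=(0.5, 7.0)),  # overlaps the reference band
            dict(fc_rerun_cutoff=5.0),
            dict(filter_order=3),
            dict(power_def="rms"),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            bl.DetectorConfig(**kwargs)
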