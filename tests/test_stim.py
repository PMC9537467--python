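"""Phase-locked scheduling: delay arithmetic, closed loop, circular scoring."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as spstats

import biologger as bl
from biologger.stim import NoStimTrialsError, wrap_degrees


class TestPhaseDelay:
    def test_already_on_target_needs_no_delay(self):
        assert bl.phase_delay(2.5, 270.0, 0.0, 270.0) == 0.0

    def test_half_period_to_opposite_phase(self):
        assert bl.phase_delay(1.0, 0.0, 0.0, 180.0) == 500.0

    def test_latency_phase_lag_identity(self):
        # a 2.5 Hz slow wave accumulates 30 deg over 33.33 ms of latency
        assert bl.latency_phase_lag(2.5, 100.0 / 3.0) == pytest.approx(30.0)
        assert bl.latency_phase_lag(1.0, 1000.0) == pytest.approx(360.0)

    def test_delay_wraps_past_latency_floor(self):
        # target reachable at 8 ms, but latency forces the next cycle
        d = bl.phase_delay(2.5, 262.8, 50.0, 270.0, scheduling_resolution_ms=0.001)
        assert d >= 50.0
        assert d == pytest.approx(8.0 + 400.0, abs=0.01)

    def test_nonpositive_fc_rejected(self):
        with pytest.raises(ValueError):
            bl.phase_delay(0.0, 0.0, 0.0, 270.0)

    @given(
        fc=st.floats(0.5, 4.0),
        phase=st.floats(0.0, 360.0, exclude_max=True),
        latency=st.floats(0.0, 60.0),
        res=st.sampled_from([0.25, 0.5, 1.0, 2.0]),
    )
    def test_delay_floor_and_quantization(self, fc, phase, latency, res):
        d = bl.phase_delay(fc, phase, latency, 270.0, scheduling_resolution_ms=res)
        assert d >= latency - 1e-9
        assert (d / res) == pytest.approx(round(d / res), abs=1e-6)
        # quantization error is at most half a step plus the bump
        exact = bl.phase_delay(fc, phase, latency, 270.0, scheduling_resolution_ms=1e-7)
        assert abs(d - exact) <= res + 1e-6


@pytest.fixture(scope="module")
def pure_sw_recording():
    return bl.sinusoid_recording(2.5, 150.0, duration=300.0)


@pytest.fixture(scope="module")
def fast_det_config():
    # short refractory packs many trials into a short recording
    return bl.DetectorConfig(refractory_s=0.5)


class TestSimulateClosedLoop:
    def test_fixed_latency_hits_target_phase(self, pure_sw_recording):
        latency = bl.LatencyModel(wireless_dist="fixed")
        trials = bl.simulate_closed_loop(
            pure_sw_recording, bl.DetectorConfig(), latency, sham_prob=0.0, seed=1
        )
        summary = bl.evaluate_phase_accuracy(trials)
        assert summary.n_stim >= 50
        assert summary.mean_abs_error_deg <= 1.5

    def test_all_sham_delivers_no_tones(self, pure_sw_recording, fast_det_config):
        trials = bl.simulate_closed_loop(
            pure_sw_recording, fast_det_config, bl.LatencyModel(), sham_prob=1.0, seed=2
        )
        assert len(trials) > 0
        assert all(t.plan.sham and t.marker == "red" for t in trials)
        with pytest.raises(NoStimTrialsError):
            bl.evaluate_phase_accuracy(trials)

    def test_sham_fraction_within_binomial_ci(self, pure_sw_recording, fast_det_config):
        trials = bl.simulate_closed_loop(
            pure_sw_recording, fast_det_config, bl.LatencyModel(), sham_prob=0.1, seed=3
        )
        n = len(trials)
        assert n >= 500
        k = sum(t.plan.sham for t in trials)
        lo, hi = spstats.binom.interval(0.99, n, 0.1)
        assert lo <= k <= hi

    def test_same_seed_reproduces_trials_exactly(self, pure_sw_recording, fast_det_config):
        kw = dict(det_config=fast_det_config, latency=bl.LatencyModel(), sham_prob=0.1)
        a = bl.simulate_closed_loop(pure_sw_recording, seed=7, **kw)
        b = bl.simulate_closed_loop(pure_sw_recording, seed=7, **kw)
        assert [t.plan for t in a] == [t.plan for t in b]
        assert [t.achieved_phase for t in a] == pytest.approx(
            [t.achieved_phase for t in b], nan_ok=True
        )

    def test_peri_data_spans_four_seconds(self, pure_sw_recording):
        trials = bl.simulate_closed_loop(
            pure_sw_recording, bl.DetectorConfig(), bl.LatencyModel(), seed=0
        )
        assert all(t.peri_data.size == 4 * 125 for t in trials)

    def test_detection_near_end_dropped_with_warning(self):
        # second detection (t = 6 s) falls within 2 s of the 7.5-s end
        rec = bl.sinusoid_recording(2.5, 150.0, duration=7.5)
        with pytest.warns(UserWarning, match="peri-detection"):
            trials = bl.simulate_closed_loop(
                rec, bl.DetectorConfig(), bl.LatencyModel(), seed=0
            )
        assert len(trials) == 1

    def test_tone_center_never_precedes_latency(self, pure_sw_recording, fast_det_config):
        latency = bl.LatencyModel(wireless_dist="gaussian", wireless_sd_ms=5.0)
        trials = bl.simulate_closed_loop(
            pure_sw_recording, fast_det_config, latency, sham_prob=0.0, seed=4
        )
        # the drawn latency is not exposed per trial, but its floor is
        assert all(t.plan.delay_ms >= latency.algo_ms_full for t in trials)

    def test_error_grows_with_wireless_jitter(self, pure_sw_recording, fast_det_config):
        errors = []
        for sd in (0.0, 4.0, 10.0):
            latency = bl.LatencyModel(wireless_dist="gaussian", wireless_sd_ms=sd)
            trials = bl.simulate_closed_loop(
                pure_sw_recording, fast_det_config, latency, sham_prob=0.0, seed=5
            )
            summary = bl.evaluate_phase_accuracy(trials)
            assert summary.n_stim >= 200
            errors.append(summary.mean_abs_error_deg)
        assert errors == sorted(errors)

    def test_perfect_compensation_limit(self):
        # fixed latency + vanishing scheduling resolution: error -> 0
        rec = bl.sinusoid_recording(2.0, 150.0, duration=120.0)
        latency = bl.LatencyModel(wireless_dist="fixed", scheduling_resolution_ms=1e-6)
        trials = bl.simulate_closed_loop(
            rec, bl.DetectorConfig(), latency, sham_prob=0.0, seed=6
        )
        summary = bl.evaluate_phase_accuracy(trials)
        assert summary.mean_abs_error_deg < 0.01


class TestEvaluatePhaseAccuracy:
    def _trial(self, achieved, target=270.0, sham=False):
        det = bl.DetectionResult(time=10.0, trial_number=0, fc=2.5, phase_at_fc=0.0)
        plan = bl.StimulusPlan(delay_ms=100.0, target_phase=target, sham=sham)
        return bl.ClosedLoopTrial(
            detection=det,
            plan=plan,
            peri_data=np.zeros(500),
            achieved_phase=achieved,
            marker="red" if sham else "green",
        )

    def test_exact_hits_score_zero(self):
        s = bl.evaluate_phase_accuracy([self._trial(270.0), self._trial(270.0)])
        assert s.mean_abs_error_deg == 0.0

    def test_symmetric_misses_average_to_their_magnitude(self):
        s = bl.evaluate_phase_accuracy([self._trial(280.0), self._trial(260.0)])
        assert s.mean_abs_error_deg == pytest.approx(10.0)

    def test_errors_wrap_around_the_circle(self):
        s = bl.evaluate_phase_accuracy(
            [self._trial(350.0, target=0.0), self._trial(10.0, target=0.0)]
        )
        assert s.mean_abs_error_deg == pytest.approx(10.0)

    def test_shams_excluded_but_counted(self):
        s = bl.evaluate_phase_accuracy(
            [self._trial(270.0), self._trial(float("nan"), sham=True)]
        )
        assert s.n_stim == 1 and s.n_sham == 1


class TestLatencyModel:
    def test_defaults_are_the_measured_device_figures(self):
        m = bl.LatencyModel()
        assert (m.algo_ms_full, m.algo_ms_tail) == (20.06, 25.55)
        assert (m.wireless_mean_ms, m.wireless_sd_ms) == (10.17, 1.74)

    def test_fixed_draw_returns_the_mean(self):
        m = bl.LatencyModel(wireless_dist="fixed")
        assert m.draw_wireless(np.random.default_rng(0)) == 10.17

    def test_gaussian_draws_are_nonnegative_and_seeded(self):
        m = bl.LatencyModel(wireless_dist="gaussian", wireless_sd_ms=20.0)
        a = [m.draw_wireless(np.random.default_rng(1)) for _ in range(3)]
        b = [m.draw_wireless(np.random.default_rng(1)) for _ in range(3)]
        assert a == b
        draws = [m.draw_wireless(np.random.default_rng(i)) for i in range(200)]
        assert min(draws) >= 0.0

    def test_tail_runtime_cannot_undercut_full(self):
        with pytest.raises(ValueError):
            bl.LatencyModel(algo_ms_full=20.0, algo_ms_tail=10.0)


def test_wrap_degrees_is_odd_and_bounded():
    d = wrap_degrees([0.0, 180.0, 181.0, 359.0, -359.0, 720.0])
    assert list(d) == [0.0, 180.0, -179.0, -1.0, 1.0, 0.0]
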