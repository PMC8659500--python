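"""Calving stage: transitions, rolling bout count, trigger and alarms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import calfwatch as cw
from calfwatch.calving import rolling_bout_count, transitions


RATE = 0.27
STEP_MS = 1000.0 / RATE


def times(n):
    return (np.arange(n, dtype=float) + 1) * STEP_MS


def make_stat(f_lb, window_s=18000.0, lb_valid=None):
    n = len(f_lb)
    f_lb = np.asarray(f_lb, dtype=np.int8)
    lb_valid = (np.ones(n, dtype=bool) if lb_valid is None
                else np.asarray(lb_valid))
    seg = np.zeros(n, dtype=np.intp)
    f_part, part_valid = rolling_bout_count(f_lb, lb_valid, seg, RATE, window_s)
    return cw.BoutStatistic(times(n), f_lb, lb_valid, f_part, part_valid,
                            seg, RATE, window_s)


class TestTransitions:
    def run(self, f_standing):
        f_standing = np.asarray(f_standing, dtype=np.int8)
        n = len(f_standing)
        return transitions(f_standing, np.ones(n, dtype=bool),
                           np.zeros(n, dtype=np.intp))

    def test_constant_input_all_zero(self):
        f_lb, valid = self.run([1] * 10)
        assert not f_lb[valid].any()

    def test_alternating_input(self):
        f_lb, valid = self.run([0, 1, 0, 1])
        assert not valid[0]  # first sample carries no value
        np.testing.assert_array_equal(f_lb[1:], [1, 1, 1])

    def test_noiseless_transition_count_equals_truth(self, noiseless_case):
        schedule, _scenario, stream, params = noiseless_case
        stat = cw.bout_statistic(cw.compute_posture(stream, params))
        assert stat.n_transitions() == schedule.n_transitions


class TestRollingBoutCount:
    def test_three_isolated_transitions(self):
        f_lb = np.zeros(6000, dtype=np.int8)
        f_lb[[5000, 5200, 5400]] = 1
        stat = make_stat(f_lb)
        assert stat.f_parturition[-1] == 3

    def test_transition_older_than_window_is_excluded(self):
        w = 10
        window_s = w / RATE
        f_lb = np.zeros(30, dtype=np.int8)
        f_lb[5] = 1
        stat = make_stat(f_lb, window_s=window_s)
        # the window (t - w, t] holds indices i-w+1 .. i
        assert stat.f_parturition[5 + w - 1] == 1
        assert stat.f_parturition[5 + w] == 0  # one step past the window

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 600),
           w=st.integers(1, 40))
    def test_property_equivalence_with_brute_force(self, seed, n, w):
        rng = np.random.default_rng(seed)
        f_lb = (rng.uniform(size=n) < 0.1).astype(np.int8)
        stat = make_stat(f_lb, window_s=w / RATE)
        brute = np.array([f_lb[max(0, i - w + 1): i + 1].sum()
                          for i in range(n)])
        np.testing.assert_array_equal(stat.f_parturition, brute)

    def test_monotone_response_to_added_transition(self):
        rng = np.random.default_rng(4)
        f_lb = (rng.uniform(size=400) < 0.05).astype(np.int8)
        stat = make_stat(f_lb, window_s=50 / RATE)
        zero = np.nonzero(f_lb == 0)[0][20]
        bumped = f_lb.copy()
        bumped[zero] = 1
        stat2 = make_stat(bumped, window_s=50 / RATE)
        assert np.all(stat2.f_parturition >= stat.f_parturition)


class TestTrigger:
    def test_max_plus_margin(self):
        f_lb = np.zeros(30_000, dtype=np.int8)
        f_lb[28_000:28_018:2] = 1  # a 9-transition burst
        stat = make_stat(f_lb)
        model = cw.fit_trigger(stat, calibration_end_ms=stat.times_ms[-1],
                               margin=1)
        assert stat.f_parturition.max() == 9
        assert model.trigger_value == 10

    def test_constant_zero_baseline_gives_margin(self):
        stat = make_stat(np.zeros(30_000, dtype=np.int8))
        model = cw.fit_trigger(stat, calibration_end_ms=stat.times_ms[-1],
                               margin=2)
        assert model.trigger_value == 2

    def test_insufficient_calibration_data_errors(self):
        stat = make_stat(np.zeros(6000, dtype=np.int8))
        with pytest.raises(ValueError, match="24"):
            cw.fit_trigger(stat, calibration_end_ms=stat.times_ms[-1],
                           min_hours=24)


class TestDetect:
    def make_detection(self, gate=None):
        f_lb = np.zeros(40_000, dtype=np.int8)
        f_lb[30_000:30_030:2] = 1  # a late 15-transition burst
        stat = make_stat(f_lb)
        model = cw.TriggerModel(cow_id="c", trigger_value=5.0,
                                calibration_hours=24.0, gate_ms=gate)
        return stat, model

    def test_quiet_series_no_alarms(self):
        stat = make_stat(np.zeros(30_000, dtype=np.int8))
        model = cw.TriggerModel(cow_id="c", trigger_value=5.0,
                                calibration_hours=24.0)
        assert cw.detect_parturition(stat, model).alarms == []

    def test_refractory_yields_single_alarm(self):
        stat, model = self.make_detection()
        result = cw.detect_parturition(stat, model)
        assert len(result.alarms) == 1
        assert result.alarms[0].value > 5

    def test_out_of_gate_exceedance_suppressed_and_logged(self, caplog):
        stat, model = self.make_detection(gate=(0.0, 1000.0))
        with caplog.at_level("WARNING"):
            result = cw.detect_parturition(stat, model)
        assert result.alarms == []
        assert len(result.suppressed) == 1
        assert any("suppressed" in r.message for r in caplog.records)

    def test_alarm_log_csv(self, tmp_path):
        stat, model = self.make_detection()
        result = cw.detect_parturition(stat, model)
        cw.write_alarm_log(result, tmp_path / "alarms.csv")
        text = (tmp_path / "alarms.csv").read_text()
        assert "gated_out" in text and "c," in text


class TestLeadTime:
    def alarm_at(self, t_ms):
        return cw.DetectionResult(alarms=[cw.Alarm(t_ms, 11, 10.0, True)])

    def test_two_hours_early(self):
        truth = 100 * 3600_000.0
        assert cw.lead_time(self.alarm_at(truth - 2 * 3600_000.0), truth) == 2.0

    def test_on_time_and_late(self):
        truth = 50 * 3600_000.0
        assert cw.lead_time(self.alarm_at(truth), truth) == 0.0
        assert cw.lead_time(self.alarm_at(truth + 3600_000.0), truth) == -1.0

    def test_no_alarm_is_undefined_not_zero(self):
        assert cw.lead_time(cw.DetectionResult(), 0.0) is None


class TestStreaming:
    def test_bout_tracker_matches_batch(self):
        rng = np.random.default_rng(12)
        f_standing = (rng.uniform(size=8000) < 0.5).astype(np.int8)
        valid = np.ones(8000, dtype=bool)
        seg = np.zeros(8000, dtype=np.intp)
        f_lb, lb_valid = transitions(f_standing, valid, seg)
        f_part, part_valid = rolling_bout_count(f_lb, lb_valid, seg, RATE,
                                                window_s=500 / RATE)
        tracker = cw.BoutTracker(RATE, window_s=500 / RATE)
        for i, s in enumerate(f_standing):
            lb, part = tracker.push(int(s))
            assert tracker.state_size <= tracker.window_samples + 1
            if lb_valid[i]:
                assert lb == f_lb[i]
            if part_valid[i]:
                assert part == f_part[i]
            elif lb_valid[i]:
                assert part is None
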