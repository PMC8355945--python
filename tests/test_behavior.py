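"""Behavioral segmentation: interval classes, buzz/capture events, commute."""

import numpy as np
import pytest

from echowing import behavior, coupling, kinematics, night
from echowing.kinematics import WingbeatCycle
from echowing.simulate import FlightPlan, SegmentSpec, generate_flight, render_accel, simulate_recording
from echowing import acoustics

from conftest import make_calls


def buzz_call_times(n_buzzI=10, ivI_ms=10.0, n_buzzII=12, ivII_ms=5.0, t0=1.0):
    """Call times for one approach->buzz sequence preceded by slow calls."""
    slow = [t0 - 0.45, t0 - 0.3, t0 - 0.15]
    tI = t0 + np.arange(n_buzzI) * ivI_ms / 1e3
    tII = tI[-1] + ivII_ms / 1e3 + np.arange(n_buzzII) * ivII_ms / 1e3
    return np.concatenate([slow, tI, tII]), len(slow)


class TestIntervalClasses:
    @pytest.mark.parametrize(
        "interval_ms,expected",
        [
            (5.0, "buzzII"),
            (10.0, "buzzI"),
            (14.0, "multi-per-wingbeat"),  # half-open boundary rule
            (50.0, "multi-per-wingbeat"),
            (150.0, "one-per-wingbeat"),
            (300.0, "one-per-2-wingbeats"),
            (450.0, "one-per-3-wingbeats"),
            (700.0, "unclassified"),
        ],
    )
    def test_default_bins(self, interval_ms, expected):
        calls = make_calls([0.0, interval_ms / 1e3])
        out = behavior.classify_intervals(calls)
        assert out.interval_class.iloc[1] == expected

    def test_first_call_unclassified(self):
        out = behavior.classify_intervals(make_calls([0.0, 0.15]))
        assert out.interval_class.iloc[0] == "unclassified"

    def test_negative_interval_rejected(self):
        calls = make_calls([0.0, 0.15])
        calls.loc[1, "interval_prev_ms"] = -5.0
        with pytest.raises(ValueError):
            behavior.classify_intervals(calls)

    def test_figure_preset_bins(self):
        # the alternative preset uses a 5-7 / 8-14 ms split
        out = behavior.classify_intervals(make_calls([0.0, 0.0075]), bins=behavior.FIG_INTERVAL_BINS)
        assert out.interval_class.iloc[1] == "unclassified"
        out = behavior.classify_intervals(make_calls([0.0, 0.009]), bins=behavior.FIG_INTERVAL_BINS)
        assert out.interval_class.iloc[1] == "buzzI"


class TestBuzzDetection:
    def test_single_capture_structure(self):
        times, n_slow = buzz_call_times()
        calls = behavior.classify_intervals(make_calls(times))
        events = behavior.detect_buzzes(calls)
        assert len(events) == 1
        ev = events[0]
        # capture = last buzz call; buzz II sub-run starts at the 11th buzz call
        assert ev.t_capture == times[-1]
        assert ev.call_indices[0] == n_slow  # first buzz I call starts the run
        assert ev.buzzII_indices[0] == n_slow + 10
        assert len(ev.buzzII_indices) == 12

    def test_commute_only_no_events(self):
        calls = behavior.classify_intervals(make_calls(np.arange(50) * 0.143))
        assert behavior.detect_buzzes(calls) == []

    def test_min_run_gate(self):
        times, _ = buzz_call_times(n_buzzI=2, n_buzzII=1)
        calls = behavior.classify_intervals(make_calls(times))
        assert behavior.detect_buzzes(calls, min_run=5) == []

    def test_pause_merges_runs(self):
        # two fast runs separated by a 50 ms pause merge into one event
        t1 = np.arange(8) * 0.010
        t2 = t1[-1] + 0.05 + np.arange(8) * 0.005
        calls = behavior.classify_intervals(make_calls(np.concatenate([[-0.5], t1, t2])))
        events = behavior.detect_buzzes(calls)
        assert len(events) == 1
        assert events[0].t_capture == t2[-1]

    def test_distant_runs_stay_separate(self):
        t1 = np.arange(8) * 0.010
        t2 = t1[-1] + 0.5 + np.arange(8) * 0.005
        calls = behavior.classify_intervals(make_calls(np.concatenate([[-0.5], t1, t2])))
        assert len(behavior.detect_buzzes(calls)) == 2

    def test_require_buzzII_flag(self):
        times, _ = buzz_call_times(n_buzzI=8, n_buzzII=0)
        calls = behavior.classify_intervals(make_calls(times))
        assert len(behavior.detect_buzzes(calls, require_buzzII=False)) == 1
        assert len(behavior.detect_buzzes(calls, require_buzzII=True)) == 0

    def test_full_night_counting_path(self):
        # truth-level night: 48 captures recovered, buzz calls < 2% of all calls
        stats = night.night_buzz_fraction(seed=5, n_captures=12, search_s=170.0)
        assert stats["n_events"] == 12
        assert stats["buzz_fraction"] < 0.02


class TestAerialFlag:
    def make_cycles(self, t0, t1, f=10.0, amp=8.0):
        edges = np.arange(t0, t1, 1.0 / f)
        return [WingbeatCycle(a, (a + b) / 2, b, amp) for a, b in zip(edges[:-1], edges[1:])]

    def test_flying_buzz_is_aerial(self):
        ev = behavior.CaptureEvent(t_buzz_start=5.0, t_buzzII_start=5.05, t_capture=5.1)
        cycles = self.make_cycles(0.0, 10.0)
        assert behavior.flag_aerial(ev, cycles, accel_span=(0.0, 10.0)) is True

    def test_buzz_at_rest_not_aerial(self):
        ev = behavior.CaptureEvent(t_buzz_start=5.0, t_buzzII_start=5.05, t_capture=5.1)
        cycles = self.make_cycles(0.0, 2.0)  # flight ended long before
        assert behavior.flag_aerial(ev, cycles, accel_span=(0.0, 10.0)) is False

    def test_no_accel_overlap_unknown(self):
        ev = behavior.CaptureEvent(t_buzz_start=50.0, t_buzzII_start=50.05, t_capture=50.1)
        assert behavior.flag_aerial(ev, self.make_cycles(0.0, 2.0), accel_span=(0.0, 10.0)) is None

    def test_gleaning_plan_produces_no_aerial_capture(self):
        # ground gleaning: low source levels, 200-500 ms intervals, no flight
        plan = FlightPlan(
            [SegmentSpec("gleaning", 20.0, 0.0, 0.0, call_interval_ms=(200.0, 500.0), sl_efd_db=55.0)],
            seed=13,
        )
        truth, rec = simulate_recording(plan, noise_floor_db=20.0)
        calls = acoustics.analyze_audio(rec.audio_pa, rec.fs_audio)
        calls = behavior.classify_intervals(calls)
        assert behavior.detect_buzzes(calls) == []  # long intervals: no buzz at all
        filt = kinematics.lowpass_accel(rec.accel_z_ms2)
        assert kinematics.detect_wingbeats(filt) == []  # no wingbeats on the ground


@pytest.fixture(scope="module")
def commute_120s():
    plan = FlightPlan(
        [SegmentSpec("commute", 120.0, 7.0, 5.0, calls_per_wingbeat=1, phase_spread_deg=20.0)],
        seed=14,
    )
    truth = generate_flight(plan)
    filt = kinematics.lowpass_accel(render_accel(truth))
    cycles = kinematics.detect_wingbeats(filt)
    calls = make_calls(truth.calls.time_s)
    return behavior.classify_intervals(calls), cycles


class TestCommuteDetection:
    def test_long_commute_found(self, commute_120s):
        calls, cycles = commute_120s
        segs = behavior.detect_commute(calls, cycles)
        assert len(segs) == 1
        assert segs[0].t_end - segs[0].t_start >= 100.0

    def test_interrupting_capture_breaks_commute(self, commute_120s):
        calls, cycles = commute_120s
        mid = behavior.CaptureEvent(t_buzz_start=60.0, t_buzzII_start=60.05, t_capture=60.1)
        assert behavior.detect_commute(calls, cycles, events=[mid]) == []

    def test_wrong_wingbeat_band_rejected(self):
        plan = FlightPlan(
            [SegmentSpec("approach", 120.0, 11.0, 6.0, calls_per_wingbeat=1, phase_spread_deg=20.0)],
            seed=15,
        )
        truth = generate_flight(plan)
        cycles = kinematics.detect_wingbeats(kinematics.lowpass_accel(render_accel(truth)))
        calls = behavior.classify_intervals(make_calls(truth.calls.time_s))
        assert behavior.detect_commute(calls, cycles) == []  # 11 Hz outside 6-8 Hz band


class TestApproachOnset:
    def make_scene(self, counts):
        cycles = [WingbeatCycle(i * 0.1, i * 0.1 + 0.05, (i + 1) * 0.1, 8.0) for i in range(len(counts))]
        ev = behavior.CaptureEvent(
            t_buzz_start=cycles[-1].t_start + 0.01,
            t_buzzII_start=cycles[-1].t_start + 0.05,
            t_capture=cycles[-1].t_end - 0.01,
        )
        return ev, np.asarray(counts), cycles

    def test_onset_at_first_sustained_multicall_cycle(self):
        ev, counts, cycles = self.make_scene([1, 1, 1, 2, 3, 2, 3, 11])
        t = behavior.detect_approach_onset(ev, counts, cycles)
        assert t == pytest.approx(cycles[3].t_start)

    def test_interrupted_run_restarts(self):
        ev, counts, cycles = self.make_scene([2, 2, 1, 2, 3, 11])
        t = behavior.detect_approach_onset(ev, counts, cycles)
        assert t == pytest.approx(cycles[3].t_start)

    def test_fallback_to_buzz_start(self):
        ev, counts, cycles = self.make_scene([1, 1, 1, 1, 1, 11])
        t = behavior.detect_approach_onset(ev, counts, cycles)
        assert t == ev.t_buzz_start

    def test_onset_on_simulated_capture(self):
        summary, ana = night.roundtrip_summary(seed=6, n_captures=2, commute_s=10.0)
        for ev in ana.events:
            assert ev.t_approach_onset is not None
            # approach starts well before the buzz (three 0.6 s stages)
            assert ev.t_buzz_start - ev.t_approach_onset > 0.5


class TestSegmentation:
    def test_partition_covers_span(self):
        summary, ana = night.roundtrip_summary(seed=7, n_captures=2, commute_s=10.0)
        segs = ana.segments
        span = (0.0, len(ana.recording.accel_z_ms2) / ana.recording.fs_accel)
        assert segs[0].t_start == span[0] and segs[-1].t_end == pytest.approx(span[1])
        for a, b in zip(segs[:-1], segs[1:]):
            assert b.t_start == pytest.approx(a.t_end)  # no gaps, no overlaps
        assert all(s.t_end > s.t_start for s in segs)
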