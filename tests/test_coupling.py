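"""Coupling metrics: phase joins, per-wingbeat energy, circular statistics."""

import numpy as np
import pytest
from scipy import stats

from echowing import behavior, coupling, kinematics, night
from echowing.kinematics import WingbeatCycle
from echowing.simulate import render_accel

from conftest import make_calls


def grid_circular_median(angles, step=0.05):
    """Independent brute-force minimizer of mean circular deviation."""
    cand = np.arange(0.0, 360.0, step)
    d = np.abs((angles[None, :] - cand[:, None] + 180.0) % 360.0 - 180.0)
    return cand[np.argmin(d.mean(axis=1))]


def cost(angles, m):
    return np.abs((angles - m + 180.0) % 360.0 - 180.0).mean()


class TestCircularStats:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_median_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 1000))
        a = (rng.normal(200, 80, n) + 360 * rng.integers(0, 2, n) * 0) % 360
        est = coupling.circular_median(a)
        ref = grid_circular_median(a)
        assert cost(a, est) <= cost(a, ref) + 1e-9

    def test_median_wraps_across_zero(self):
        rng = np.random.default_rng(4)
        a = (rng.normal(0, 20, 500)) % 360  # mass straddling 0/360
        est = coupling.circular_median(a)
        assert abs(coupling.circular_diff_deg(est, 0.0)) < 3.0

    def test_quartile_recovery_135_235(self):
        # construct a sample whose quartiles are exactly (135, 235) around 176
        rng = np.random.default_rng(5)
        off = rng.normal(0, 1, 4001)
        off = (off - np.median(off)) / (np.percentile(off, 75) - np.percentile(off, 25))
        a = (176.0 + off * 100.0 + 9.0) % 360.0  # quartile range 100 deg, q25 at ~135
        q25, q75 = coupling.circular_quartiles(a)
        assert coupling.circular_diff_deg(q75, q25) == pytest.approx(100.0, abs=10.0)
        assert abs(coupling.circular_diff_deg(q25, 135.0)) < 10.0
        assert abs(coupling.circular_diff_deg(q75, 235.0)) < 10.0


class TestPhaseAssignment:
    def test_commute_phase_recovery(self, commute_recording):
        from echowing import acoustics

        truth, rec = commute_recording
        calls = acoustics.analyze_audio(rec.audio_pa, rec.fs_audio)
        filt = kinematics.lowpass_accel(rec.accel_z_ms2)
        cycles = kinematics.detect_wingbeats(filt)
        phase = kinematics.compute_phase(len(filt), cycles)
        calls = coupling.assign_phase(calls, phase)
        med = coupling.circular_median(calls.phase_deg.to_numpy())
        assert abs(coupling.circular_diff_deg(med, 176.0)) < 5.0

    def test_call_outside_flight_has_no_phase(self):
        phase = kinematics.compute_phase(2000, [WingbeatCycle(0.1, 0.17, 0.24, 8.0)])
        calls = coupling.assign_phase(make_calls([0.15, 1.5]), phase)
        assert np.isfinite(calls.phase_deg.iloc[0])
        assert np.isnan(calls.phase_deg.iloc[1])


class TestPerWingbeatMetrics:
    def cycles_1hz(self, n=5):
        return [WingbeatCycle(float(i), i + 0.5, float(i + 1), 8.0) for i in range(n)]

    def test_two_calls_sum_in_energy_domain(self):
        calls = make_calls([0.2, 0.6], sl_efd=70.0)
        m = coupling.per_wingbeat_metrics(calls, self.cycles_1hz())
        assert m.summed_efd_db.iloc[0] == pytest.approx(73.01, abs=0.01)
        assert m.n_calls.iloc[0] == 2

    def test_single_call_sum_is_identity(self):
        calls = make_calls([1.5], sl_efd=85.0)
        m = coupling.per_wingbeat_metrics(calls, self.cycles_1hz())
        assert m.summed_efd_db.iloc[1] == pytest.approx(85.0)

    def test_empty_cycle_is_nan_sentinel(self):
        calls = make_calls([0.2], sl_efd=85.0)
        m = coupling.per_wingbeat_metrics(calls, self.cycles_1hz())
        assert np.isnan(m.summed_efd_db.iloc[3])

    def test_energy_conservation(self):
        rng = np.random.default_rng(6)
        t = np.sort(rng.uniform(0, 5, 200))
        lv = rng.uniform(50, 90, 200)
        calls = make_calls(t)
        calls["sl_efd"] = lv
        cycles = self.cycles_1hz()
        m = coupling.per_wingbeat_metrics(calls, cycles)
        total_cycles = np.nansum(10 ** (m.summed_efd_db / 10.0))
        assigned = coupling.assign_cycles(calls, cycles) != coupling.UNCYCLED
        total_calls = np.sum(10 ** (lv[assigned] / 10.0))
        assert total_cycles == pytest.approx(total_calls, rel=1e-9)

    def test_uncycled_bucket(self):
        calls = make_calls([0.5, 7.5])  # second call beyond last cycle
        idx = coupling.assign_cycles(calls, self.cycles_1hz())
        assert idx[0] == 0 and idx[1] == coupling.UNCYCLED
        assert len(coupling.uncycled_calls(calls, self.cycles_1hz())) == 1

    def test_buzz_cycle_energy_drop(self):
        # 11 weak calls (30 dB down) sum ~19.6 dB below one loud search call
        cycles = self.cycles_1hz(2)
        calls = make_calls(list(np.linspace(0.1, 0.9, 11)) + [1.5])
        calls["sl_efd"] = [52.0] * 11 + [82.0]
        m = coupling.per_wingbeat_metrics(calls, cycles)
        drop = m.summed_efd_db.iloc[1] - m.summed_efd_db.iloc[0]
        assert drop == pytest.approx(30.0 - 10 * np.log10(11), abs=0.01)


class TestCaptureAlignment:
    def test_flat_commute_control(self, commute_recording):
        truth, rec = commute_recording
        filt = kinematics.lowpass_accel(rec.accel_z_ms2)
        cycles = kinematics.detect_wingbeats(filt)
        calls = make_calls(truth.calls.time_s)
        m = coupling.per_wingbeat_metrics(calls, cycles)
        fake_event = behavior.CaptureEvent(t_buzz_start=9.0, t_buzzII_start=9.0, t_capture=9.5)
        aligned = coupling.align_to_capture([fake_event], m)
        assert np.allclose(aligned.n_calls_mean, 1.0)

    def test_buzz_rise_and_energy_fall(self):
        summary, ana = night.roundtrip_summary(seed=8, n_captures=4, commute_s=10.0)
        al = ana.aligned
        # calls/wingbeat rises toward capture while summed energy falls
        assert al.n_calls_mean.iloc[-1] > al.n_calls_mean.iloc[0] + 3
        assert al.summed_efd_db_mean.iloc[-1] < al.summed_efd_db_mean.iloc[0] - 10
        # wingbeat frequency increases toward the capture
        assert al.frequency_hz_mean.iloc[-1] > al.frequency_hz_mean.iloc[0] + 3

    def test_short_history_padded_with_nan(self):
        cycles = [WingbeatCycle(float(i), i + 0.5, float(i + 1), 8.0) for i in range(3)]
        calls = make_calls([0.5, 1.5, 2.5])
        m = coupling.per_wingbeat_metrics(calls, cycles)
        ev = behavior.CaptureEvent(t_buzz_start=2.0, t_buzzII_start=2.2, t_capture=2.5)
        aligned = coupling.align_to_capture([ev], m, n_cycles=10)
        assert np.isnan(aligned.n_calls_mean.iloc[0])  # index -10 has no data
        assert aligned.n_calls_mean.iloc[-1] == 1.0


class TestPhaseHistogram:
    def test_uniform_phases_flat(self):
        rng = np.random.default_rng(9)
        calls = make_calls(np.sort(rng.uniform(0, 100, 3600)))
        calls["phase_deg"] = rng.uniform(0, 360, 3600)
        calls["interval_class"] = "one-per-wingbeat"
        h = coupling.phase_histogram(calls)["one-per-wingbeat"]
        chi = stats.chisquare(h["counts"])
        assert chi.pvalue > 0.01

    def test_small_class_suppressed(self):
        calls = make_calls(np.arange(5) * 0.1)
        calls["phase_deg"] = [10.0, 20.0, 30.0, 40.0, 50.0]
        calls["interval_class"] = "buzzII"
        h = coupling.phase_histogram(calls)["buzzII"]
        assert h["normalized"] is None
        assert h["counts"].sum() == 5


class TestLevelVsInterval:
    def test_constant_levels_flat_no_transition(self):
        rng = np.random.default_rng(10)
        calls = make_calls(np.sort(rng.uniform(0, 50, 500)), sl_efd=82.0)
        out = coupling.level_vs_interval(calls)
        occupied = out[out.n > 0]
        assert occupied.median_db.nunique() == 1
        assert not out.transition.any()

    def test_transition_band_localized(self):
        # loud calls at 150/75 ms, weak calls below 60 ms: drop between 60 and 75
        rng = np.random.default_rng(11)
        iv = np.concatenate([
            np.full(200, 150.0), np.full(200, 75.0),
            np.full(200, 55.0), np.full(200, 30.0), np.full(200, 8.0),
        ])
        lv = np.concatenate([np.full(400, 82.0), np.full(600, 62.0)])
        t = np.cumsum(iv) / 1e3
        calls = make_calls(t)
        calls["interval_prev_ms"] = iv
        calls["sl_efd"] = lv
        out = coupling.level_vs_interval(calls)
        band = out[out.transition]
        assert len(band) == 2
        lo, hi = band.interval_lo_ms.min(), band.interval_hi_ms.max()
        assert lo <= 60.0 <= hi and lo <= 75.0 <= hi

    def test_no_calls_rejected(self):
        with pytest.raises(ValueError):
            coupling.level_vs_interval(make_calls([]))


def test_calls_per_second_integrates_to_total():
    rng = np.random.default_rng(12)
    t = np.sort(rng.uniform(0, 30, 444))
    hist = coupling.calls_per_second_histogram(make_calls(t), (0.0, 30.0))
    assert hist.calls_per_s.sum() == 444
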