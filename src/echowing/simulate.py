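"""Ground-truthed synthetic tag recordings.

Emulates the sound-and-movement tag carried by a foraging bat: a heave
(dorso-ventral) accelerometer channel sampled at 1 kHz dominated by the
sinusoidal wingbeat oscillation around gravity, and an ultrasonic audio
channel at 187.5 kHz carrying FM echolocation calls over a noise floor.
Call emission follows the behavioral state: phase-locked to the wingbeat
cycle in commute/search (one call per 1-3 wingbeats near the end of the
upstroke), several calls per wingbeat in approach, and interval-scheduled
trains in the terminal buzz (buzz I: 7-14 ms intervals, buzz II: 4-7 ms).

Everything is deterministic given the plan seed; the generator returns a
truth table (call times, phases, source levels, capture times) against
which the downstream detectors can be scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

G_MS2 = 9.82  # gravity as used throughout the phase convention, m/s^2
P_REF = 20e-6  # reference pressure, Pa
ACCEL_FS = 1000.0  # accelerometer sampling rate, Hz
AUDIO_FS = 187_500.0  # audio sampling rate, Hz
ACCEL_CLIP_G = 8.0  # accelerometer clip level, g
AUDIO_CLIP_DB = 121.0  # audio clip level, dB re 20 uPa
OFF_AXIS_DB = 14.0  # scalar off-axis -> on-axis source-level correction, dB

#: states whose calls are scheduled by inter-call interval rather than phase
INTERVAL_STATES = ("buzzI", "buzzII", "gleaning")
FLIGHTLESS_STATES = ("rest", "gleaning")

_DEFAULT_CALL_DURATION_MS = {"buzzI": 0.5, "buzzII": 0.5}
_FALLBACK_CALL_DURATION_MS = 3.0  # the fixed-duration convention for search calls

IntervalSpec = Union[float, tuple]
CallsPerWingbeat = Union[float, tuple]


@dataclass
class SegmentSpec:
    """One behavioral segment of a simulated flight.

    Calls are scheduled either by wingbeat phase (``calls_per_wingbeat``:
    values <= 1 mean one call every round(1/x) wingbeats; integers >= 2 or an
    (lo, hi) integer range mean that many calls per wingbeat, spaced
    ``phase_step_deg`` apart starting at the phase center — evenly around
    the cycle, 360/k, when left as None) or by inter-call
    interval (``call_interval_ms``: a scalar for fixed spacing or an (lo, hi)
    band for uniform draws).  Exactly one of the two may be set.
    """

    state: str
    duration_s: float
    wingbeat_hz: float = 0.0
    accel_amp_ms2: float = 0.0
    calls_per_wingbeat: Optional[CallsPerWingbeat] = None
    call_interval_ms: Optional[IntervalSpec] = None
    sl_efd_db: float = 82.0
    phase_center_deg: float = 176.0
    phase_spread_deg: float = 0.0
    phase_step_deg: Optional[float] = None
    call_duration_ms: Optional[float] = None


@dataclass
class FlightPlan:
    """An ordered list of behavioral segments plus the master seed."""

    segments: Sequence[SegmentSpec]
    seed: int = 0
    blend_s: float = 0.5  # wingbeat-frequency ramp window at segment boundaries

    def validate(self) -> None:
        if not self.segments:
            raise ValueError("plan has no segments")
        for seg in self.segments:
            if seg.duration_s <= 0:
                raise ValueError(f"segment duration must be > 0, got {seg.duration_s}")
            if not 0.0 <= seg.wingbeat_hz <= 20.0:
                raise ValueError(f"wingbeat frequency {seg.wingbeat_hz} outside [0, 20] Hz")
            if seg.wingbeat_hz == 0.0 and seg.state not in FLIGHTLESS_STATES:
                raise ValueError(f"wingbeat frequency 0 only allowed for rest/gleaning, not {seg.state}")
            if seg.calls_per_wingbeat is not None and seg.call_interval_ms is not None:
                raise ValueError("segment cannot schedule calls by both phase and interval")
            if seg.call_interval_ms is not None:
                lo, hi = _interval_band(seg.call_interval_ms)
                if lo < 4.0:
                    raise ValueError(f"call interval {lo} ms below the 4 ms buzz II band")
                if seg.state == "buzzII" and not (4.0 <= lo and hi < 7.0 + 1e-9):
                    raise ValueError("buzz II intervals must lie in [4, 7) ms")
                if seg.state == "buzzI" and not (7.0 <= lo and hi < 14.0 + 1e-9):
                    raise ValueError("buzz I intervals must lie in [7, 14) ms")
            if seg.calls_per_wingbeat is not None and seg.wingbeat_hz == 0.0:
                raise ValueError("phase-scheduled calls require a nonzero wingbeat frequency")

    @property
    def duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.segments))


def _interval_band(spec: IntervalSpec) -> tuple:
    if np.isscalar(spec):
        return float(spec), float(spec)
    lo, hi = spec
    if hi < lo:
        raise ValueError(f"interval band ({lo}, {hi}) inverted")
    return float(lo), float(hi)


@dataclass
class GroundTruth:
    """True state of a simulated flight: continuous phase plus call/capture tables."""

    plan: FlightPlan
    fs: float
    t: np.ndarray  # sample times, includes the trailing record pad
    phase_unwrapped_deg: np.ndarray
    freq_hz: np.ndarray
    amp_ms2: np.ndarray
    calls: pd.DataFrame  # time_s, phase_deg, sl_efd_db, duration_ms, state
    segments: pd.DataFrame  # state, t_start, t_end
    capture_times: np.ndarray
    duration_s: float
    pad_s: float

    @property
    def phase_deg(self) -> np.ndarray:
        return np.mod(self.phase_unwrapped_deg, 360.0)

    @property
    def flying(self) -> np.ndarray:
        return self.freq_hz > 0.0


@dataclass
class TagRecording:
    """Synchronized audio + accelerometer streams with sampling metadata."""

    audio_pa: np.ndarray
    fs_audio: float
    accel_z_ms2: np.ndarray
    fs_accel: float
    clip_db: float = AUDIO_CLIP_DB
    clip_fraction: float = 0.0
    t0: float = 0.0


def _profile(plan: FlightPlan, t: np.ndarray) -> tuple:
    """Per-sample wingbeat frequency and accel amplitude with linear blends.

    Knots sit inside each segment (offset by min(blend/2, duration/3) from
    either edge) so np.interp produces a linear ramp across every boundary,
    clamped for segments shorter than the blend window.
    """
    knot_t, knot_f, knot_a = [], [], []
    t0 = 0.0
    for seg in plan.segments:
        off = min(plan.blend_s / 2.0, seg.duration_s / 3.0)
        knot_t.extend([t0 + off, t0 + seg.duration_s - off])
        knot_f.extend([seg.wingbeat_hz] * 2)
        knot_a.extend([seg.accel_amp_ms2] * 2)
        t0 += seg.duration_s
    f = np.interp(t, knot_t, knot_f)
    a = np.interp(t, knot_t, knot_a)
    return f, a


def generate_flight(plan: FlightPlan, pad_s: float = 0.02) -> GroundTruth:
    """Lay out the continuous wingbeat phase and the true call schedule.

    Phase advances at 360 * f_wb deg/s, frequency ramping linearly across
    segment boundaries; it freezes during flightless segments.  Calls in
    phase-scheduled states land at the segment's emission-phase center plus
    zero-mean Gaussian jitter of the stated spread; buzz/gleaning calls are
    placed by interval starting at the segment start.  Deterministic for a
    given plan seed.  The record runs ``pad_s`` past the behavioral plan
    (the tag keeps logging) so the final wingbeat closes.
    """
    plan.validate()
    rng = np.random.default_rng(np.random.SeedSequence(plan.seed).spawn(1)[0])
    fs = ACCEL_FS
    total = plan.duration_s
    n = int(round((total + pad_s) * fs)) + 1
    t = np.arange(n) / fs
    freq, amp = _profile(plan, np.minimum(t, total))  # pad continues the last segment
    phase = np.concatenate([[0.0], np.cumsum(360.0 * freq[:-1] / fs)])

    seg_rows, rows = [], []
    t0 = 0.0
    for seg in plan.segments:
        t1 = t0 + seg.duration_s
        seg_rows.append({"state": seg.state, "t_start": t0, "t_end": t1})
        dur_ms = seg.call_duration_ms
        if dur_ms is None:
            dur_ms = _DEFAULT_CALL_DURATION_MS.get(seg.state, _FALLBACK_CALL_DURATION_MS)
        if seg.call_interval_ms is not None:
            times = _schedule_by_interval(seg, t0, t1, rng)
        elif seg.calls_per_wingbeat is not None:
            times = _schedule_by_phase(seg, t0, t1, t, phase, fs, rng)
        else:
            times = np.empty(0)
        for tc in times:
            rows.append(
                {
                    "time_s": tc,
                    "phase_deg": float(np.interp(tc, t, phase) % 360.0),
                    "sl_efd_db": seg.sl_efd_db,
                    "duration_ms": dur_ms,
                    "state": seg.state,
                }
            )
        t0 = t1

    calls = pd.DataFrame(rows, columns=["time_s", "phase_deg", "sl_efd_db", "duration_ms", "state"])
    calls = calls.sort_values("time_s", kind="stable").reset_index(drop=True)
    calls = _enforce_min_gap(calls, min_gap_ms=4.0)
    segments = pd.DataFrame(seg_rows, columns=["state", "t_start", "t_end"])
    capture_times = _true_capture_times(calls, segments)
    return GroundTruth(
        plan=plan,
        fs=fs,
        t=t,
        phase_unwrapped_deg=phase,
        freq_hz=freq,
        amp_ms2=amp,
        calls=calls,
        segments=segments,
        capture_times=capture_times,
        duration_s=total,
        pad_s=pad_s,
    )


def _enforce_min_gap(calls: pd.DataFrame, min_gap_ms: float) -> pd.DataFrame:
    """Drop calls violating the vocal-motor floor on inter-call intervals.

    Phase jitter can occasionally schedule two calls closer than a bat can
    physically produce them (the buzz II band bottoms out at 4 ms); the
    later call of such a pair is discarded.
    """
    if len(calls) < 2:
        return calls
    keep = np.ones(len(calls), dtype=bool)
    t = calls["time_s"].to_numpy()
    last = t[0]
    for i in range(1, len(t)):
        if (t[i] - last) * 1e3 < min_gap_ms:
            keep[i] = False
        else:
            last = t[i]
    return calls[keep].reset_index(drop=True)


def _schedule_by_interval(seg: SegmentSpec, t0: float, t1: float, rng) -> np.ndarray:
    lo, hi = _interval_band(seg.call_interval_ms)
    times = []
    tc = t0
    while tc < t1 - 1e-12:
        times.append(tc)
        step = lo if lo == hi else rng.uniform(lo, hi)
        tc += step / 1000.0
    return np.asarray(times)


def _schedule_by_phase(seg: SegmentSpec, t0: float, t1: float, t, phase, fs, rng) -> np.ndarray:
    i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
    p0, p1 = phase[i0], phase[min(i1, len(phase) - 1)]
    pseg = phase[i0 : i1 + 1]
    tseg = t[i0 : i1 + 1]
    spec = seg.calls_per_wingbeat
    m0 = int(np.ceil(p0 / 360.0))
    m1 = int(np.floor(p1 / 360.0))
    targets = []
    if np.isscalar(spec) and spec <= 1.0:
        step = max(1, int(round(1.0 / float(spec))))
        for m in range(m0, m1 + 1, step):
            targets.append(360.0 * m + seg.phase_center_deg + rng.normal(0.0, seg.phase_spread_deg))
    else:
        if np.isscalar(spec):
            lo = hi = int(spec)
        else:
            lo, hi = int(spec[0]), int(spec[1])
        for m in range(m0, m1 + 1):
            c = lo if lo == hi else int(rng.integers(lo, hi + 1))
            step = seg.phase_step_deg if seg.phase_step_deg is not None else 360.0 / c
            for j in range(c):
                targets.append(
                    360.0 * m
                    + seg.phase_center_deg
                    + j * step
                    + rng.normal(0.0, seg.phase_spread_deg)
                )
    targets = np.asarray(sorted(targets))
    targets = targets[(targets >= p0) & (targets <= p1)]
    times = np.interp(targets, pseg, tseg)
    return times[(times >= t0) & (times < t1)]


def _true_capture_times(calls: pd.DataFrame, segments: pd.DataFrame) -> np.ndarray:
    """A capture ends each maximal run of buzz segments: time of its last call."""
    captures = []
    in_buzz = False
    last_call = None
    for _, seg in segments.iterrows():
        if seg.state in ("buzzI", "buzzII"):
            in_buzz = True
            sel = calls[(calls.time_s >= seg.t_start) & (calls.time_s < seg.t_end)]
            if len(sel):
                last_call = float(sel.time_s.iloc[-1])
        else:
            if in_buzz and last_call is not None:
                captures.append(last_call)
            in_buzz = False
            last_call = None
    if in_buzz and last_call is not None:
        captures.append(last_call)
    return np.asarray(captures)


def render_accel(
    truth: GroundTruth,
    noise_sd: float = 0.0,
    harmonic_db: Optional[float] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Heave acceleration a_z(t) = g - A(t) sin(phase) (+ harmonic + noise).

    With this sign convention a_z dips below gravity exactly during the
    upstroke half of the cycle (phase 0-180 deg).  An optional second
    harmonic (level in dB relative to the fundamental) makes spectral peak
    tracking nontrivial.  Clipped at +/- 8 g.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    if seed is None:
        seed = np.random.SeedSequence(truth.plan.seed).spawn(3)[1]
    rng = np.random.default_rng(seed)
    rad = np.deg2rad(truth.phase_unwrapped_deg)
    a = G_MS2 - truth.amp_ms2 * np.sin(rad)
    a[~truth.flying] = G_MS2
    if harmonic_db is not None:
        h = truth.amp_ms2 * 10.0 ** (harmonic_db / 20.0) * np.sin(2.0 * rad)
        h[~truth.flying] = 0.0
        a = a + h
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=a.shape)
    clip = ACCEL_CLIP_G * 9.80665
    return np.clip(a, -clip, clip)


def fm_sweep(
    duration_s: float,
    fs: float = AUDIO_FS,
    f_start: float = 80e3,
    f_end: float = 25e3,
) -> np.ndarray:
    """Unit-amplitude Hann-enveloped linear FM downsweep."""
    n = max(int(round(duration_s * fs)), 8)
    tau = np.arange(n) / fs
    inst_phase = 2.0 * np.pi * (f_start * tau + (f_end - f_start) / (2.0 * duration_s) * tau**2)
    return np.hanning(n) * np.sin(inst_phase)


def efd_db(p: np.ndarray, fs: float) -> float:
    """Energy flux density of a pressure snippet, dB re 20 uPa^2 s."""
    e = float(np.sum(np.square(p, dtype=np.float64))) / fs
    return 10.0 * np.log10(e / P_REF**2)


def render_audio(
    truth: GroundTruth,
    noise_floor_db: float = 30.0,
    clip_db: float = AUDIO_CLIP_DB,
    fs: float = AUDIO_FS,
    f_start: float = 80e3,
    f_end: float = 25e3,
    seed: Optional[int] = None,
) -> tuple:
    """Render the audio stream in Pa; returns (audio, clip_fraction).

    Each true call becomes an FM downsweep centered on its scheduled time,
    scaled so its on-tag energy flux density equals the true source level
    minus the 14 dB off-axis correction.  Gaussian noise sets the floor
    (RMS level in dB re 20 uPa).  Samples are hard-clipped at the tag's
    clip level and the clipped fraction reported.
    """
    if seed is None:
        seed = np.random.SeedSequence(truth.plan.seed).spawn(3)[2]
    rng = np.random.default_rng(seed)
    n = int(round((truth.duration_s + truth.pad_s) * fs)) + 1
    noise_rms = P_REF * 10.0 ** (noise_floor_db / 20.0)
    audio = rng.standard_normal(n, dtype=np.float32) * np.float32(noise_rms)

    wave_cache: dict = {}
    clip_pa = P_REF * 10.0 ** (clip_db / 20.0)
    for _, call in truth.calls.iterrows():
        d = call.duration_ms / 1000.0
        if d < 0.3e-3:
            raise ValueError(f"call duration {call.duration_ms} ms below 0.3 ms floor")
        key = round(call.duration_ms, 6)
        if key not in wave_cache:
            w = fm_sweep(d, fs, f_start, f_end)
            wave_cache[key] = (w, efd_db(w, fs))
        w, efd_unit = wave_cache[key]
        apparent = call.sl_efd_db - OFF_AXIS_DB
        if apparent > clip_db:
            warnings.warn(
                f"apparent call level {apparent:.1f} dB exceeds clip level {clip_db} dB; clipping",
                stacklevel=2,
            )
        amp = 10.0 ** ((apparent - efd_unit) / 20.0)
        c = int(round(call.time_s * fs))
        i0 = c - len(w) // 2
        j0, j1 = max(i0, 0), min(i0 + len(w), n)
        if j1 > j0:
            audio[j0:j1] += (amp * w[j0 - i0 : j1 - i0]).astype(np.float32)

    clipped = np.count_nonzero(np.abs(audio) > clip_pa)
    np.clip(audio, -clip_pa, clip_pa, out=audio)
    return audio, clipped / n


def simulate_recording(
    plan: FlightPlan,
    accel_noise_sd: float = 0.0,
    noise_floor_db: float = 30.0,
    harmonic_db: Optional[float] = None,
    clip_db: float = AUDIO_CLIP_DB,
) -> tuple:
    """Full simulation: (GroundTruth, TagRecording) with independent per-stream seeds."""
    truth = generate_flight(plan)
    ss = np.random.SeedSequence(plan.seed).spawn(3)
    accel = render_accel(truth, noise_sd=accel_noise_sd, harmonic_db=harmonic_db, seed=ss[1])
    audio, clip_frac = render_audio(truth, noise_floor_db=noise_floor_db, clip_db=clip_db, seed=ss[2])
    rec = TagRecording(
        audio_pa=audio,
        fs_audio=AUDIO_FS,
        accel_z_ms2=accel,
        fs_accel=ACCEL_FS,
        clip_db=clip_db,
        clip_fraction=clip_frac,
    )
    return truth, rec
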