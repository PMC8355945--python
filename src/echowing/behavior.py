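"""Rule-based behavioral segmentation of the call/motion record.

Call intervals map directly onto behavioral state in this species: slow
wingbeat-locked intervals (>=100 ms) during commute/search, tens of ms in
the approach, 7-14 ms in buzz I and 4-7 ms in buzz II, the terminal phase
of an aerial prey capture.  The capture time is the emission time of the
last buzz call.  The approach onset is located automatically as the point
from which the bat sustains >= 2 calls per wingbeat through to the buzz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from echowing.kinematics import WingbeatCycle

#: half-open interval bins (lo_ms, hi_ms, label); behavioral definitions preset
DEFAULT_INTERVAL_BINS = [
    (4.0, 7.0, "buzzII"),
    (7.0, 14.0, "buzzI"),
    (14.0, 100.0, "multi-per-wingbeat"),
    (100.0, 200.0, "one-per-wingbeat"),
    (200.0, 400.0, "one-per-2-wingbeats"),
    (400.0, 600.0, "one-per-3-wingbeats"),
]

#: alternative preset following the phase-histogram figure convention
FIG_INTERVAL_BINS = [
    (5.0, 7.0, "buzzII"),
    (8.0, 14.0, "buzzI"),
    (14.0, 100.0, "multi-per-wingbeat"),
    (100.0, 200.0, "one-per-wingbeat"),
    (200.0, 400.0, "one-per-2-wingbeats"),
    (400.0, 600.0, "one-per-3-wingbeats"),
]

SLOW_CLASSES = ("one-per-wingbeat", "one-per-2-wingbeats", "one-per-3-wingbeats")


@dataclass
class Segment:
    state: str
    t_start: float
    t_end: float


@dataclass
class CaptureEvent:
    """A buzz-terminated prey-capture attempt."""

    t_buzz_start: float
    t_buzzII_start: float
    t_capture: float  # emission time of the last buzz call
    call_indices: List[int] = field(default_factory=list)
    buzzII_indices: List[int] = field(default_factory=list)
    t_approach_onset: Optional[float] = None
    is_aerial: Optional[bool] = None


def classify_intervals(calls: pd.DataFrame, bins=None) -> pd.DataFrame:
    """Attach ``interval_class`` per call from its interval to the previous call.

    Bins are half-open [lo, hi); intervals outside every bin (including the
    first call's undefined interval) are 'unclassified'.  Negative
    intervals mean a corrupt record and are rejected.
    """
    if bins is None:
        bins = DEFAULT_INTERVAL_BINS
    iv = calls["interval_prev_ms"].to_numpy(dtype=float)
    if np.any(iv[np.isfinite(iv)] < 0):
        raise ValueError("negative call interval: record not time-ordered")
    labels = np.full(len(calls), "unclassified", dtype=object)
    for lo, hi, name in bins:
        labels[(iv >= lo) & (iv < hi)] = name
    out = calls.copy()
    out["interval_class"] = labels
    return out


def detect_buzzes(
    calls: pd.DataFrame,
    min_run: int = 5,
    buzz_max_ms: float = 14.0,
    buzzII_max_ms: float = 7.0,
    max_gap_ms: float = 100.0,
    require_buzzII: bool = False,
) -> List[CaptureEvent]:
    """Capture events as maximal runs of fast-interval (buzz) calls.

    A run is >= ``min_run`` consecutive calls with interval < 14 ms, plus
    the call that starts it; runs separated by <= ``max_gap_ms`` (buzz I
    pauses) merge into one event.  The buzz II sub-run is the terminal
    stretch with intervals < 7 ms; the capture time is the last call of
    the run.  With ``require_buzzII`` a buzz I-only run is dropped
    (by default it still counts as a capture attempt).
    """
    iv = calls["interval_prev_ms"].to_numpy(dtype=float)
    t = calls["t_peak"].to_numpy(dtype=float)
    fast = np.isfinite(iv) & (iv < buzz_max_ms)

    # raw runs of consecutive fast calls, each extended to its predecessor
    runs = []
    i = 0
    n = len(calls)
    while i < n:
        if fast[i]:
            j = i
            while j + 1 < n and fast[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                runs.append([max(i - 1, 0), j])
            i = j + 1
        else:
            i += 1

    # merge runs split by short pauses
    merged = []
    for run in runs:
        if merged and (t[run[0]] - t[merged[-1][1]]) * 1e3 <= max_gap_ms:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    events = []
    for i0, i1 in merged:
        idx = list(range(i0, i1 + 1))
        # terminal sub-run with interval below the buzz II bound
        k = i1
        while k > i0 and np.isfinite(iv[k]) and iv[k] < buzzII_max_ms:
            k -= 1
        buzzII_idx = list(range(k + 1, i1 + 1))
        if require_buzzII and not buzzII_idx:
            continue
        events.append(
            CaptureEvent(
                t_buzz_start=float(t[i0]),
                t_buzzII_start=float(t[buzzII_idx[0]]) if buzzII_idx else float(t[i1]),
                t_capture=float(t[i1]),
                call_indices=idx,
                buzzII_indices=buzzII_idx,
            )
        )
    return events


def label_buzz_calls(calls: pd.DataFrame, events: Sequence[CaptureEvent]) -> pd.DataFrame:
    """Attach a ``buzz`` label column: none / buzzI / buzzII per call."""
    labels = np.full(len(calls), "none", dtype=object)
    for ev in events:
        labels[ev.call_indices] = "buzzI"
        labels[ev.buzzII_indices] = "buzzII"
    out = calls.copy()
    out["buzz"] = labels
    return out


def flag_aerial(
    event: CaptureEvent,
    cycles: Sequence[WingbeatCycle],
    accel_span: Optional[tuple] = None,
    amp_threshold_ms2: float = 1.0,
    min_coverage: float = 0.8,
    lead_s: float = 0.5,
) -> Optional[bool]:
    """Was the bat flying through the buzz?  (Excludes landing/gleaning buzzes.)

    True iff wingbeat cycles with amplitude above threshold cover at least
    ``min_coverage`` of [t_buzz_start - lead, t_capture].  ``accel_span``
    is the (t0, t1) extent of the accelerometer record; None is returned
    (aerial status unknown) when it does not overlap the window.
    """
    w0, w1 = event.t_buzz_start - lead_s, event.t_capture
    if w1 <= w0:
        return None
    if accel_span is not None and (accel_span[1] <= w0 or accel_span[0] >= w1):
        return None
    if accel_span is None and not any(c.t_end > w0 and c.t_start < w1 for c in cycles):
        # without the record extent, absent wingbeats are indistinguishable
        # from absent data only when no cycles overlap at all
        return None
    covered = 0.0
    for c in cycles:
        if c.amplitude_ms2 < amp_threshold_ms2:
            continue
        covered += max(0.0, min(c.t_end, w1) - max(c.t_start, w0))
    event.is_aerial = bool(covered / (w1 - w0) >= min_coverage)
    return event.is_aerial


def detect_commute(
    calls: pd.DataFrame,
    cycles: Sequence[WingbeatCycle],
    events: Sequence[CaptureEvent] = (),
    t_span: Optional[tuple] = None,
    min_duration_s: float = 100.0,
    slow_fraction: float = 0.9,
    freq_band_hz: tuple = (6.0, 8.0),
) -> List[Segment]:
    """Commuting-flight stretches: long, buzz-free, wingbeat-locked calling.

    A commute segment is a maximal window of at least ``min_duration_s``
    containing no capture event, in which >= 90% of calls fall in the slow
    wingbeat-locked interval classes and the median wingbeat frequency sits
    in the 6-8 Hz commuting band.
    """
    if "interval_class" not in calls:
        calls = classify_intervals(calls)
    if t_span is None:
        t_lo = 0.0
        t_hi = max(
            calls["t_peak"].max() if len(calls) else 0.0,
            cycles[-1].t_end if cycles else 0.0,
        )
    else:
        t_lo, t_hi = t_span

    # candidate stretches between capture events
    bounds = [t_lo]
    for ev in sorted(events, key=lambda e: e.t_buzz_start):
        bounds.extend([ev.t_buzz_start, ev.t_capture])
    bounds.append(t_hi)

    segments = []
    freqs = np.array([c.frequency_hz for c in cycles])
    starts = np.array([c.t_start for c in cycles])
    tp = calls["t_peak"].to_numpy(dtype=float)
    slow = calls["interval_class"].isin(SLOW_CLASSES).to_numpy()
    for k in range(0, len(bounds), 2):
        w0, w1 = bounds[k], bounds[k + 1]
        if w1 - w0 < min_duration_s:
            continue
        in_w = (tp >= w0) & (tp < w1)
        if in_w.sum() == 0:
            continue
        if slow[in_w].mean() < slow_fraction:
            continue
        in_c = (starts >= w0) & (starts < w1)
        if in_c.sum() == 0:
            continue
        med_f = float(np.median(freqs[in_c]))
        if not freq_band_hz[0] <= med_f <= freq_band_hz[1]:
            continue
        segments.append(Segment("commute", w0, w1))
    return segments


def detect_approach_onset(
    event: CaptureEvent,
    cycle_call_counts: np.ndarray,
    cycles: Sequence[WingbeatCycle],
    window_s: float = 5.0,
    min_calls_per_wingbeat: int = 2,
    min_consecutive: int = 2,
) -> float:
    """Approach onset: earliest cycle from which >= 2 calls/wingbeat holds to the buzz.

    Scans wingbeat cycles within ``window_s`` before the capture for the
    earliest cycle such that every cycle from it through the one containing
    the buzz start carries at least ``min_calls_per_wingbeat`` calls, with
    at least ``min_consecutive`` such cycles.  Falls back to the buzz start
    when the criterion is never met (degenerate fast attack).
    """
    starts = np.array([c.t_start for c in cycles])
    ends = np.array([c.t_end for c in cycles])
    in_buzz = np.nonzero((starts <= event.t_buzz_start) & (ends > event.t_buzz_start))[0]
    if len(in_buzz) == 0:
        event.t_approach_onset = event.t_buzz_start
        return event.t_buzz_start
    cb = int(in_buzz[0])
    onset_idx = None
    i = cb
    # walk backwards while the calls-per-wingbeat criterion holds
    while i >= 0 and cycles[i].t_start >= event.t_capture - window_s:
        if cycle_call_counts[i] >= min_calls_per_wingbeat:
            onset_idx = i
            i -= 1
        else:
            break
    if onset_idx is None or cb - onset_idx + 1 < min_consecutive:
        event.t_approach_onset = event.t_buzz_start
    else:
        event.t_approach_onset = float(cycles[onset_idx].t_start)
    return event.t_approach_onset


def segment_record(
    events: Sequence[CaptureEvent],
    commutes: Sequence[Segment],
    t_span: tuple,
) -> List[Segment]:
    """Partition of the analyzed span into labeled, non-overlapping segments.

    Capture events contribute approach/buzzI/buzzII stretches, commute
    segments their span; everything else is 'unknown'.  The output covers
    [t_span] exactly with no gaps or overlaps.
    """
    marks = []
    for ev in sorted(events, key=lambda e: e.t_buzz_start):
        onset = ev.t_approach_onset if ev.t_approach_onset is not None else ev.t_buzz_start
        if onset < ev.t_buzz_start:
            marks.append(Segment("approach", onset, ev.t_buzz_start))
        if ev.t_buzzII_start > ev.t_buzz_start:
            marks.append(Segment("buzzI", ev.t_buzz_start, ev.t_buzzII_start))
        if ev.t_capture > ev.t_buzzII_start:
            marks.append(Segment("buzzII", ev.t_buzzII_start, ev.t_capture))
    marks.extend(Segment(s.state, s.t_start, s.t_end) for s in commutes)
    marks.sort(key=lambda s: s.t_start)

    out: List[Segment] = []
    cursor = t_span[0]
    for m in marks:
        if m.t_start > cursor:
            out.append(Segment("unknown", cursor, m.t_start))
        if m.t_end > cursor:
            out.append(Segment(m.state, max(m.t_start, cursor), m.t_end))
            cursor = m.t_end
    if cursor < t_span[1]:
        out.append(Segment("unknown", cursor, t_span[1]))
    return out


def segments_to_frame(segments: Sequence[Segment]) -> pd.DataFrame:
    return pd.DataFrame([{"state": s.state, "t_start": s.t_start, "t_end": s.t_end} for s in segments])
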