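"""Vocal-locomotor coupling metrics: calls joined to wingbeat cycles.

Couples the detected call table to the wingbeat-phase series: per-call
emission phase, per-wingbeat call counts and summed call energy (energy
flux density summed in the linear domain), capture-aligned time series
over the last ten wingbeats, circular phase histograms by interval class,
and the source-level-versus-interval summary.

Circular statistics follow the convention that the median minimizes the
mean circular absolute deviation and quartiles are the 25%/75% cumulative
mass around that median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from echowing.kinematics import PhaseSeries, WingbeatCycle

UNCYCLED = -1  # cycle index sentinel for calls outside every wingbeat cycle


def assign_phase(calls: pd.DataFrame, phase: PhaseSeries) -> pd.DataFrame:
    """Attach ``phase_deg``: the wingbeat phase at each call's peak time.

    NaN where no wingbeat cycle covers the call (bat not in detected
    flight); 0-180 deg is the upstroke by convention.
    """
    out = calls.copy()
    out["phase_deg"] = phase.phase_at(calls["t_peak"].to_numpy(dtype=float))
    return out


def assign_cycles(calls: pd.DataFrame, cycles: Sequence[WingbeatCycle]) -> np.ndarray:
    """Index of the unique cycle containing each call (UNCYCLED if none)."""
    starts = np.array([c.t_start for c in cycles])
    ends = np.array([c.t_end for c in cycles])
    t = calls["t_peak"].to_numpy(dtype=float)
    if len(cycles) == 0:
        return np.full(len(t), UNCYCLED)
    idx = np.searchsorted(starts, t, side="right") - 1
    idx = np.clip(idx, 0, len(cycles) - 1)
    inside = (t >= starts[idx]) & (t < ends[idx])
    return np.where(inside, idx, UNCYCLED)


def per_wingbeat_metrics(
    calls: pd.DataFrame,
    cycles: Sequence[WingbeatCycle],
    level_column: str = "sl_efd",
) -> pd.DataFrame:
    """Per-cycle call count, call rate, mean frequency and summed EFD.

    Summed EFD adds member calls in the energy (linear) domain:
    10 log10(sum 10^(L_i/10)); cycles with no calls carry NaN (sentinel),
    never a -inf that could leak into downstream arithmetic.
    """
    cyc_idx = assign_cycles(calls, cycles)
    n = len(cycles)
    counts = np.zeros(n, dtype=int)
    energy = np.zeros(n, dtype=float)
    levels = calls[level_column].to_numpy(dtype=float)
    for i, k in enumerate(cyc_idx):
        if k == UNCYCLED:
            continue
        counts[k] += 1
        energy[k] += 10.0 ** (levels[i] / 10.0)
    with np.errstate(divide="ignore"):
        summed = np.where(counts > 0, 10.0 * np.log10(np.maximum(energy, 1e-300)), np.nan)
    return pd.DataFrame(
        {
            "cycle": np.arange(n),
            "t_start": [c.t_start for c in cycles],
            "t_end": [c.t_end for c in cycles],
            "n_calls": counts,
            "call_rate_hz": counts / np.array([c.duration_s for c in cycles]),
            "frequency_hz": [c.frequency_hz for c in cycles],
            "summed_efd_db": summed,
        }
    )


def uncycled_calls(calls: pd.DataFrame, cycles: Sequence[WingbeatCycle]) -> pd.DataFrame:
    """Calls falling outside every detected wingbeat cycle."""
    return calls[assign_cycles(calls, cycles) == UNCYCLED]


def align_to_capture(
    events,
    metrics: pd.DataFrame,
    n_cycles: int = 10,
) -> pd.DataFrame:
    """Capture-aligned mean +/- sd of the per-wingbeat metrics.

    Wingbeat index -1 is the cycle containing the capture time, -2 the one
    before, etc.  Events with fewer than ``n_cycles`` preceding cycles
    contribute missing leading values.  Averages of summed EFD are taken
    in the dB domain (the figure-style mean level).
    """
    cols = ["n_calls", "call_rate_hz", "frequency_hz", "summed_efd_db"]
    stacks = {c: np.full((len(events), n_cycles), np.nan) for c in cols}
    t_start = metrics["t_start"].to_numpy()
    t_end = metrics["t_end"].to_numpy()
    for e, ev in enumerate(events):
        inside = np.nonzero((t_start <= ev.t_capture) & (t_end > ev.t_capture))[0]
        if len(inside) == 0:
            continue
        last = int(inside[0])
        for j in range(n_cycles):
            k = last - j
            if k < 0:
                break
            for c in cols:
                stacks[c][e, n_cycles - 1 - j] = metrics[c].iloc[k]
    idx = np.arange(-n_cycles, 0)
    out = {"wingbeat_index": idx}
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN leading columns
        for c in cols:
            out[f"{c}_mean"] = np.nanmean(stacks[c], axis=0)
            out[f"{c}_sd"] = np.nanstd(stacks[c], axis=0)
    return pd.DataFrame(out)


# ---------------------------------------------------------------- circular stats


def circular_diff_deg(a, b):
    """Signed circular difference a - b in (-180, 180]."""
    return (np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 180.0) % 360.0 - 180.0


def _mean_circular_deviation(angles: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Mean |circular distance| from each candidate, chunked to bound memory."""
    costs = np.empty(len(candidates))
    for i0 in range(0, len(candidates), 256):
        cand = candidates[i0 : i0 + 256, None]
        d = np.abs((angles[None, :] - cand + 180.0) % 360.0 - 180.0)
        costs[i0 : i0 + 256] = d.mean(axis=1)
    return costs


def circular_median(angles_deg: np.ndarray) -> float:
    """Angle minimizing the mean circular absolute deviation.

    The cost is piecewise linear with knots at the samples and their
    antipodes, so for modest n the exact minimizer is found over that
    candidate set; for large n a 0.25 deg grid is used.
    """
    a = np.asarray(angles_deg, dtype=float) % 360.0
    a = a[np.isfinite(a)]
    if len(a) == 0:
        return np.nan
    if len(a) <= 1500:
        candidates = np.unique(np.concatenate([a, (a + 180.0) % 360.0]))
    else:
        candidates = np.arange(0.0, 360.0, 0.25)
    costs = _mean_circular_deviation(a, candidates)
    return float(candidates[np.argmin(costs)])


def circular_quartiles(angles_deg: np.ndarray, median: Optional[float] = None) -> tuple:
    """(q25, q75) as 25%/75% cumulative mass around the circular median."""
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    if median is None:
        median = circular_median(a)
    off = circular_diff_deg(a, median)
    q25, q75 = np.percentile(off, [25, 75])
    return float((median + q25) % 360.0), float((median + q75) % 360.0)


def phase_histogram(
    calls: pd.DataFrame,
    by: str = "interval_class",
    bin_deg: float = 10.0,
    min_calls: int = 10,
) -> dict:
    """Per-class circular phase histograms with circular median/quartiles.

    Returns {class: {'edges', 'counts', 'normalized', 'median', 'q25',
    'q75', 'n'}}; the normalized (peak = 1) curve is suppressed (None) for
    classes with fewer than ``min_calls`` phased calls.  Calls without a
    phase (outside detected flight) are excluded.
    """
    edges = np.arange(0.0, 360.0 + bin_deg, bin_deg)
    out = {}
    groups = calls.groupby(by) if by else [("all", calls)]
    for name, grp in groups:
        ph = grp["phase_deg"].to_numpy(dtype=float)
        ph = ph[np.isfinite(ph)]
        counts, _ = np.histogram(ph % 360.0, bins=edges)
        med = circular_median(ph) if len(ph) else np.nan
        q25, q75 = circular_quartiles(ph, med) if len(ph) else (np.nan, np.nan)
        normalized = counts / counts.max() if len(ph) >= min_calls and counts.max() > 0 else None
        out[name] = {
            "edges": edges,
            "counts": counts,
            "normalized": normalized,
            "median": med,
            "q25": q25,
            "q75": q75,
            "n": int(len(ph)),
        }
    return out


def level_vs_interval(
    calls: pd.DataFrame,
    n_bins: int = 24,
    interval_range_ms: tuple = (4.0, 1000.0),
    level_column: str = "sl_efd",
    drop_db: float = 6.0,
) -> pd.DataFrame:
    """Median and quartiles of source level per log-spaced interval bin.

    The ``transition`` flag localizes where the bat first backs off its
    output as intervals shorten: the loud plateau is the median level over
    long-interval bins (>= 100 ms, the wingbeat-locked regime); scanning
    from long to short intervals, the bins bounding the first sustained
    drop below plateau - ``drop_db`` are flagged.
    """
    if len(calls) == 0:
        raise ValueError("no calls")
    iv = calls["interval_prev_ms"].to_numpy(dtype=float)
    lv = calls[level_column].to_numpy(dtype=float)
    ok = np.isfinite(iv) & np.isfinite(lv)
    iv, lv = iv[ok], lv[ok]
    edges = np.geomspace(interval_range_ms[0], interval_range_ms[1], n_bins + 1)
    rows = []
    for b in range(n_bins):
        sel = (iv >= edges[b]) & (iv < edges[b + 1])
        if sel.sum() == 0:
            rows.append({"interval_lo_ms": edges[b], "interval_hi_ms": edges[b + 1], "n": 0,
                         "median_db": np.nan, "q25_db": np.nan, "q75_db": np.nan})
            continue
        q25, med, q75 = np.percentile(lv[sel], [25, 50, 75])
        rows.append({"interval_lo_ms": edges[b], "interval_hi_ms": edges[b + 1], "n": int(sel.sum()),
                     "median_db": med, "q25_db": q25, "q75_db": q75})
    out = pd.DataFrame(rows)
    out["transition"] = False
    occ = out.index[out["n"] > 0].to_numpy()
    long_bins = out[(out["n"] > 0) & (out["interval_lo_ms"] >= 100.0)]
    if len(occ) >= 2 and len(long_bins):
        plateau = float(long_bins["median_db"].median())
        # the faint regime is the run of weak bins rising from the shortest
        # intervals; the transition is where it meets the first loud bin
        run_top = None
        for k in occ:
            if out.median_db.iloc[k] < plateau - drop_db:
                run_top = k
            else:
                if run_top is not None:
                    out.loc[run_top, "transition"] = True
                    out.loc[k, "transition"] = True
                break
    return out


def calls_per_second_histogram(calls: pd.DataFrame, t_span: tuple, bin_s: float = 1.0) -> pd.DataFrame:
    """Distribution of instantaneous call rate (calls counted per second)."""
    edges = np.arange(t_span[0], t_span[1] + bin_s, bin_s)
    counts, _ = np.histogram(calls["t_peak"].to_numpy(dtype=float), bins=edges)
    return pd.DataFrame({"t_start": edges[:-1], "calls_per_s": counts / bin_s})
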