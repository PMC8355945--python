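"""Quick-look figures from the pipeline's CSV-backed tables.

Plotting only renders numbers already present in the tables — no metric is
computed here.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_aligned(aligned, path) -> None:
    """Capture-aligned calls/wingbeat and summed energy (last ten wingbeats)."""
    fig, ax1 = plt.subplots(figsize=(6, 4))
    x = aligned["wingbeat_index"]
    ax1.errorbar(x, aligned["n_calls_mean"], yerr=aligned["n_calls_sd"], color="purple", label="calls/wingbeat")
    ax1.set_xlabel("wingbeat index before capture")
    ax1.set_ylabel("calls per wingbeat", color="purple")
    ax2 = ax1.twinx()
    ax2.errorbar(x, aligned["summed_efd_db_mean"], yerr=aligned["summed_efd_db_sd"], color="deeppink",
                 label="summed EFD")
    ax2.set_ylabel("summed EFD (dB re 20 uPa$^2$s)", color="deeppink")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_level_vs_interval(lvi, path) -> None:
    """Source level vs call interval, transition band shaded."""
    fig, ax = plt.subplots(figsize=(6, 4))
    mid = np.sqrt(lvi["interval_lo_ms"] * lvi["interval_hi_ms"])
    ax.errorbar(mid, lvi["median_db"],
                yerr=[lvi["median_db"] - lvi["q25_db"], lvi["q75_db"] - lvi["median_db"]],
                fmt="o", ms=3)
    band = lvi[lvi["transition"]]
    if len(band):
        ax.axvspan(band["interval_lo_ms"].min(), band["interval_hi_ms"].max(), alpha=0.2, color="red")
    ax.set_xscale("log")
    ax.set_xlabel("call interval (ms)")
    ax.set_ylabel("source level (dB re 20 uPa$^2$s EFD)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_phase_histograms(hists: dict, path) -> None:
    """Circular phase histograms per interval class (counts, normalized)."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for name, h in hists.items():
        centers = (h["edges"][:-1] + h["edges"][1:]) / 2
        ax1.plot(centers, h["counts"], label=f"{name} (n={h['n']})")
        if h["normalized"] is not None:
            ax2.plot(centers, h["normalized"], label=name)
    for ax in (ax1, ax2):
        ax.axvspan(0, 180, alpha=0.08, color="gray")  # upstroke
        ax.set_xlabel("wingbeat phase (deg)")
    ax1.set_ylabel("calls")
    ax2.set_ylabel("normalized")
    ax1.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_spectrogram(spec, path, dynamic_range_db: float = 30.0) -> None:
    """Wingbeat spectrogram with the peak-frequency track overlaid."""
    fig, ax = plt.subplots(figsize=(6, 4))
    mag = 20 * np.log10(np.maximum(spec.magnitude, 1e-12))
    vmax = mag.max()
    ax.pcolormesh(spec.times_s, spec.freqs_hz, mag, vmin=vmax - dynamic_range_db, vmax=vmax,
                  shading="auto")
    ok = spec.peak_valid
    ax.plot(spec.times_s[ok], spec.peak_hz[ok], "r.", ms=2)
    ax.set_ylim(0, 25)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
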