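"""File I/O: PCM WAV audio with clip-level sidecar, CSV tables, BED-like intervals.

Tag audio is exchanged as 16-bit PCM WAV where full scale corresponds to
the tag's clip level (recorded in a JSON sidecar, dB re 20 uPa), so the
pressure calibration round-trips.  Accelerometer traces, call tables,
cycles, segments and truth tables are plain CSV with header rows.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from echowing.simulate import P_REF


def write_wav(path, audio_pa: np.ndarray, fs: float, clip_db: float) -> None:
    """16-bit PCM WAV, full scale = clip level; sidecar <name>.json holds metadata."""
    path = Path(path)
    clip_pa = P_REF * 10.0 ** (clip_db / 20.0)
    scaled = np.clip(audio_pa / clip_pa, -1.0, 1.0)
    pcm = np.round(scaled * 32767.0).astype(np.int16)
    wavfile.write(path, int(fs), pcm)
    meta = {"clip_db_re_20upa": clip_db, "sample_rate_hz": fs, "encoding": "pcm16_fullscale_at_clip"}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_wav(path) -> tuple:
    """Read audio written by write_wav; returns (pressure Pa, fs, clip_db)."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    fs, pcm = wavfile.read(path)
    clip_pa = P_REF * 10.0 ** (meta["clip_db_re_20upa"] / 20.0)
    return pcm.astype(np.float64) / 32767.0 * clip_pa, float(fs), float(meta["clip_db_re_20upa"])


def write_accel_csv(path, accel: np.ndarray, fs: float) -> None:
    t = np.arange(len(accel)) / fs
    pd.DataFrame({"time_s": t, "acc_z_ms2": accel}).to_csv(path, index=False)


def read_accel_csv(path) -> tuple:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1000.0
    return df["acc_z_ms2"].to_numpy(), float(round(fs))


def write_table(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_bed(path, segments, record_id: str = "rec") -> None:
    """BED-like interval text: record id, start s, end s, state."""
    lines = [f"{record_id}\t{s.t_start:.6f}\t{s.t_end:.6f}\t{s.state}" for s in segments]
    Path(path).write_text("\n".join(lines) + "\n")


def read_mic_response(path) -> tuple:
    """Microphone response CSV (frequency Hz, gain dB) -> (freq, gain) arrays."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    return df[cols[0]].to_numpy(dtype=float), df[cols[1]].to_numpy(dtype=float)
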