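"""WAV and annotation-table I/O.

Waveforms live in memory as float64 on [-1, 1] full scale; on disk they are
16-bit PCM mono WAV. The dBFS reference is defined pre-quantization, so a
written-then-read recording measures within the 16-bit quantization floor
of the original. Detection/annotation tables round-trip through Raven-style
tab-separated selection tables for interoperability with manual review
tools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .signal import AudioSegment

__all__ = ["write_wav", "read_wav", "write_selection_table", "read_selection_table"]

RAVEN_COLUMNS = ["Selection", "Begin Time (s)", "End Time (s)",
                 "Low Freq (Hz)", "High Freq (Hz)"]


def write_wav(path, audio: AudioSegment) -> None:
    """Write mono 16-bit PCM. Values outside [-1, 1] are clipped."""
    x = np.clip(audio.samples, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(path, int(audio.sample_rate_hz), pcm)


def read_wav(path, start_s: float = 0.0) -> AudioSegment:
    sr, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("expected a mono WAV file")
    if data.dtype == np.int16:
        x = data.astype(np.float64) / 32767.0
    elif np.issubdtype(data.dtype, np.floating):
        x = data.astype(np.float64)
    else:
        info = np.iinfo(data.dtype)
        x = data.astype(np.float64) / max(abs(info.min), info.max)
    return AudioSegment(x, float(sr), start_s=start_s)


def write_selection_table(path, table: pd.DataFrame) -> None:
    """Write a Raven-style selection table (tab-separated).

    ``table`` needs columns start_s, end_s, f_low_hz, f_high_hz; any extra
    columns (score, template id, RL, source, ...) are appended after the
    standard Raven columns.
    """
    out = pd.DataFrame({
        "Selection": np.arange(1, len(table) + 1),
        "Begin Time (s)": table["start_s"].to_numpy(),
        "End Time (s)": table["end_s"].to_numpy(),
        "Low Freq (Hz)": table["f_low_hz"].to_numpy(),
        "High Freq (Hz)": table["f_high_hz"].to_numpy(),
    })
    for col in table.columns:
        if col not in ("start_s", "end_s", "f_low_hz", "f_high_hz"):
            out[col] = table[col].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_selection_table(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    missing = set(RAVEN_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"selection table missing columns: {sorted(missing)}")
    table = raw.rename(columns={
        "Begin Time (s)": "start_s", "End Time (s)": "end_s",
        "Low Freq (Hz)": "f_low_hz", "High Freq (Hz)": "f_high_hz",
    }).drop(columns=["Selection"])
    return table
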