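"""Song intensity index: a band-energy-ratio proxy for chorus level.

When many males sing at once, individual song units overlap and cannot be
segmented, so song activity is summarized by the ratio of spectral power
in the predominant song band (23-24 Hz) to power at reference background
frequencies (11 and 39 Hz), computed per 1-minute bin. Under flat
background noise the index is ~1; chorusing pushes it up. Because
numerator and denominator scale identically, the index is invariant to
overall recording gain.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .signal import SPECTROGRAM_PRESETS, AudioSegment, compute_spectrogram

__all__ = ["song_intensity_series", "mean_song_intensity"]


def song_intensity_series(audio: AudioSegment,
                          song_band: tuple[float, float] = (23.0, 24.0),
                          background_freqs: tuple[float, float] = (11.0, 39.0),
                          bin_s: float = 60.0,
                          background_halfwidth_hz: float | None = None) -> pd.DataFrame:
    """Per-bin song intensity index.

    For each ``bin_s`` bin (anchored at the audio start; a final partial
    bin is dropped): mean spectral power over bins inside ``song_band``,
    divided by the mean power at the background frequencies. By default
    each background frequency contributes the single nearest spectrogram
    bin; pass ``background_halfwidth_hz`` to average a narrow band around
    each instead. Bins whose background power is zero get NaN.

    Returns a DataFrame with columns ``bin_start_s`` and ``index``.
    """
    if audio.duration_s < bin_s:
        raise ValueError("audio shorter than one index bin")
    spec = compute_spectrogram(audio, **SPECTROGRAM_PRESETS["detection"])

    song_rows = spec.freq_slice(*song_band)
    if song_rows.size == 0:
        raise ValueError("song band contains no spectrogram bins")
    bg_rows: list[np.ndarray] = []
    for f in background_freqs:
        if background_halfwidth_hz:
            rows = spec.freq_slice(f - background_halfwidth_hz, f + background_halfwidth_hz)
        else:
            rows = np.array([int(np.argmin(np.abs(spec.freqs_hz - f)))])
        bg_rows.append(rows)

    n_bins = int(audio.duration_s // bin_s)
    starts = audio.start_s + bin_s * np.arange(n_bins)
    idx = np.full(n_bins, np.nan)
    warned = False
    for b, t0 in enumerate(starts):
        cols = spec.time_slice(t0, t0 + bin_s)
        if cols.size == 0:
            continue
        num = spec.power[np.ix_(song_rows, cols)].mean()
        # equal weight per background frequency regardless of its bin count
        bg = np.mean([spec.power[np.ix_(rows, cols)].mean() for rows in bg_rows])
        if bg <= 0:
            if not warned:
                warnings.warn("zero background power; index undefined for some bins")
                warned = True
            continue
        idx[b] = num / bg
    return pd.DataFrame({"bin_start_s": starts, "index": idx})


def mean_song_intensity(series: pd.DataFrame, window: tuple[float, float]) -> float:
    """Mean of defined bin indices whose bin_start lies in [start, end)."""
    start, end = window
    inside = series[(series["bin_start_s"] >= start) & (series["bin_start_s"] < end)]
    if inside.empty:
        raise ValueError("window covers no complete index bin")
    vals = inside["index"].dropna()
    if vals.empty:
        raise ValueError("window contains only undefined bins")
    return float(vals.mean())
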