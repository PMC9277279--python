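"""Spectrogram computation and relative received-level (dBFS) measurement.

All downstream measurements (D-call detection, song intensity, earthquake
received level) are built on one spectrogram convention: a one-sided
magnitude-squared short-time Fourier transform of a Hann-windowed frame,
with the upper half-spectrum folded in (bins other than DC/Nyquist doubled)
so that each column obeys Parseval against the windowed frame energy.

Received levels are *relative*, in dBFS: the reference is the spectrogram
energy of a full-scale DC signal occupying the same selection duration.
Only differences between dBFS values are physically meaningful; the
reference is chosen so a full-scale sine measured over the full band comes
out at the closed-form -3.01 dBFS, and rescaling a waveform by a gain g
shifts any measurement by exactly 20*log10(g).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import butter, get_window, sosfiltfilt

__all__ = [
    "AudioSegment",
    "Spectrogram",
    "Selection",
    "SPECTROGRAM_PRESETS",
    "compute_spectrogram",
    "selection_energy_dbfs",
    "quake_received_metrics",
    "EventNotFoundError",
]


#: Named STFT parameter sets. ``detection`` is the working preset for all
#: analysis; ``display`` and ``songfig`` match common figure conventions.
SPECTROGRAM_PRESETS = {
    "detection": {"n_fft": 2048, "window": "hann", "overlap_frac": 0.5},
    "display": {"n_fft": 2048, "window": "hann", "overlap_frac": 0.9},
    "songfig": {"n_fft": 3072, "window": "hann", "overlap_frac": 0.5},
}


@dataclass
class AudioSegment:
    """Mono waveform on the full-scale [-1, 1] convention.

    ``start_s`` is the segment's offset on the recording's time axis, so
    measurement results can be reported in recording time.
    """

    samples: np.ndarray
    sample_rate_hz: float
    start_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioSegment requires a mono (1-D) waveform")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    def slice(self, t_start_s: float, t_end_s: float) -> "AudioSegment":
        """Extract [t_start_s, t_end_s) in recording time, clipped to extent."""
        if t_end_s <= t_start_s:
            raise ValueError("t_end_s must exceed t_start_s")
        i0 = max(0, int(round((t_start_s - self.start_s) * self.sample_rate_hz)))
        i1 = min(self.samples.size, int(round((t_end_s - self.start_s) * self.sample_rate_hz)))
        if i1 <= i0:
            raise ValueError("requested slice does not intersect the segment")
        return AudioSegment(self.samples[i0:i1], self.sample_rate_hz,
                            start_s=self.start_s + i0 / self.sample_rate_hz)


@dataclass
class Selection:
    """A Raven-style time/frequency selection box."""

    t_min_s: float
    t_max_s: float
    f_min_hz: float
    f_max_hz: float

    def __post_init__(self) -> None:
        if not self.t_min_s < self.t_max_s:
            raise ValueError("t_min_s must be < t_max_s")
        if not self.f_min_hz < self.f_max_hz:
            raise ValueError("f_min_hz must be < f_max_hz")


@dataclass
class Spectrogram:
    """Time x frequency power matrix plus the parameters that produced it.

    ``power[i, j]`` is linear power at ``freqs_hz[i]``, frame centred at
    ``times_s[j]`` (recording time). ``window_sumsq`` is sum(w^2) for the
    analysis window, kept so energy references need no recomputation.
    """

    power: np.ndarray          # [n_freq, n_time], linear, >= 0
    freqs_hz: np.ndarray
    times_s: np.ndarray
    params: dict = field(default_factory=dict)
    window_sumsq: float = 0.0

    @property
    def hop_s(self) -> float:
        p = self.params
        return p["n_fft"] * (1.0 - p["overlap_frac"]) / p["sample_rate_hz"]

    def freq_slice(self, f_min_hz: float, f_max_hz: float) -> np.ndarray:
        """Row indices with bin centre inside [f_min_hz, f_max_hz]."""
        return np.flatnonzero((self.freqs_hz >= f_min_hz) & (self.freqs_hz <= f_max_hz))

    def time_slice(self, t_min_s: float, t_max_s: float) -> np.ndarray:
        """Column indices with frame centre inside [t_min_s, t_max_s)."""
        return np.flatnonzero((self.times_s >= t_min_s) & (self.times_s < t_max_s))


class EventNotFoundError(RuntimeError):
    """Raised when no above-threshold acoustic event exists in a search window."""


def compute_spectrogram(audio: AudioSegment, n_fft: int = 2048,
                        window: str = "hann", overlap_frac: float = 0.5) -> Spectrogram:
    """One-sided magnitude-squared STFT.

    Column count is ``floor((N - n_fft)/hop) + 1`` with
    ``hop = n_fft * (1 - overlap_frac)``; no zero padding, no boundary
    extension, so every column is a fully observed frame.
    """
    x = audio.samples
    if x.size < n_fft:
        raise ValueError(f"audio ({x.size} samples) shorter than n_fft ({n_fft})")
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError("overlap_frac must lie in [0, 1)")
    hop = int(round(n_fft * (1.0 - overlap_frac)))
    if hop < 1:
        raise ValueError("overlap_frac too close to 1 for this n_fft")

    w = get_window(window, n_fft, fftbins=True)
    frames = sliding_window_view(x, n_fft)[::hop]
    spec = np.fft.rfft(frames * w, axis=1)
    power = (spec.real ** 2 + spec.imag ** 2)
    # fold the discarded negative-frequency half back in
    power[:, 1:] *= 2.0
    if n_fft % 2 == 0:
        power[:, -1] /= 2.0
    power = power.T.copy()

    sr = audio.sample_rate_hz
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sr)
    n_frames = frames.shape[0]
    times = audio.start_s + (np.arange(n_frames) * hop + n_fft / 2.0) / sr
    params = {"n_fft": n_fft, "window": window, "overlap_frac": overlap_frac,
              "sample_rate_hz": sr}
    return Spectrogram(power=power, freqs_hz=freqs, times_s=times, params=params,
                       window_sumsq=float(np.sum(w ** 2)))


def selection_energy_dbfs(spectrogram: Spectrogram, selection: Selection) -> float:
    """Total selection energy relative to digital full scale, in dB.

    The reference is a full-scale DC signal occupying the same number of
    frames: E_ref = n_frames * n_fft * sum(w^2). With this choice the value
    is <= 0 for any unclipped waveform and rescaling the waveform by g
    shifts the result by exactly 20*log10(g).
    """
    rows = spectrogram.freq_slice(selection.f_min_hz, selection.f_max_hz)
    cols = spectrogram.time_slice(selection.t_min_s, selection.t_max_s)
    if rows.size == 0 or cols.size == 0:
        raise ValueError("selection does not intersect the spectrogram extent")
    e_sel = float(spectrogram.power[np.ix_(rows, cols)].sum())
    n_fft = spectrogram.params["n_fft"]
    e_ref = cols.size * n_fft * spectrogram.window_sumsq
    if e_sel <= 0.0:
        warnings.warn("selection contains zero energy; returning -inf dBFS")
        return float("-inf")
    return 10.0 * np.log10(e_sel / e_ref)


def _band_energy_per_frame(x: np.ndarray, sr: float, frame_s: float,
                           band_hz: tuple[float, float]) -> np.ndarray:
    """Energy of band-filtered signal in consecutive non-overlapping frames."""
    lo, hi = band_hz
    nyq = sr / 2.0
    sos = butter(4, [lo / nyq, min(hi / nyq, 0.99)], btype="bandpass", output="sos")
    y = sosfiltfilt(sos, x)
    n = int(round(frame_s * sr))
    n_frames = y.size // n
    if n_frames == 0:
        raise ValueError("audio shorter than one analysis frame")
    return (y[: n_frames * n].reshape(n_frames, n) ** 2).sum(axis=1)


def quake_received_metrics(audio: AudioSegment, expected_time: float,
                           search_pad_s: float = 120.0, k_mad: float = 5.0,
                           band_hz: tuple[float, float] = (5.0, 100.0),
                           edge_drop_db: float = 20.0,
                           min_rise_db: float = 3.0) -> dict:
    """Locate an earthquake arrival near ``expected_time`` and measure it.

    An event exists if any 1-s frame's band energy (5-100 Hz by default)
    exceeds median + k_mad * MAD over the padded search window *and* the
    peak frame rises at least ``min_rise_db`` above the median — the MAD
    criterion alone can fire on the tail of plain noise fluctuations, which
    never approach a 3 dB rise. Its extent
    is the contiguous run of frames, around the peak frame, that stay above
    ``max(noise threshold, peak - edge_drop_db)``; tying the run's edges to
    the peak keeps the measured extent (and hence the duration-normalized
    received level) stable under changes of event amplitude. Returns
    ``{"received_time_s", "rl_dbfs", "duration_s"}``.

    Raises
    ------
    EventNotFoundError
        If no frame exceeds the robust threshold (callers may fall back to
        the catalog origin time).
    """
    if not (audio.start_s <= expected_time <= audio.end_s):
        raise ValueError("expected_time lies outside the audio extent")
    t0 = max(audio.start_s, expected_time - search_pad_s)
    t1 = min(audio.end_s, expected_time + search_pad_s)
    seg = audio.slice(t0, t1)

    frame_s = 1.0
    energy = _band_energy_per_frame(seg.samples, seg.sample_rate_hz, frame_s, band_hz)
    med = np.median(energy)
    mad = np.median(np.abs(energy - med))
    thresh = med + k_mad * max(mad, np.finfo(float).tiny)
    rise_ok = energy.max() > med * 10.0 ** (min_rise_db / 10.0)
    if not ((energy > thresh).any() and rise_ok):
        raise EventNotFoundError("no frame exceeds the robust band-energy threshold")

    # extent: run around the peak frame, edges at max(noise floor, peak - drop)
    peak = int(np.argmax(energy))
    extent_thresh = max(thresh, energy[peak] * 10.0 ** (-edge_drop_db / 10.0))
    above = energy >= extent_thresh
    i0 = peak
    while i0 > 0 and above[i0 - 1]:
        i0 -= 1
    i1 = peak + 1
    while i1 < above.size and above[i1]:
        i1 += 1
    run_t0 = seg.start_s + i0 * frame_s
    run_t1 = seg.start_s + i1 * frame_s

    spec = compute_spectrogram(seg, **SPECTROGRAM_PRESETS["detection"])
    sel = Selection(run_t0, run_t1, band_hz[0], band_hz[1])
    try:
        rl = selection_energy_dbfs(spec, sel)
    except ValueError:
        # run shorter than one STFT frame: widen to the nearest frame
        pad = spec.params["n_fft"] / spec.params["sample_rate_hz"]
        rl = selection_energy_dbfs(
            spec, Selection(run_t0 - pad, run_t1 + pad, band_hz[0], band_hz[1]))
    return {"received_time_s": run_t0, "rl_dbfs": rl, "duration_s": run_t1 - run_t0}
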