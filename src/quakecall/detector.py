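"""Spectrogram-template-correlation D-call detector.

A D call is detected by sliding a library of normalized time-frequency
exemplar patches (templates) along the recording's spectrogram. At each
time lag the score is the Pearson correlation between the flattened
template and the identically shaped, band-cropped spectrogram patch; the
per-lag maximum over all templates is thresholded (default 0.80) and
collapsed to one detection per local maximum. The default library ships 13
synthetic exemplars spanning duration x sweep-rate variants of the
~100 -> 20 Hz downsweep, and accepts user-supplied exemplars.

Because the correlation operates on a zero-mean, unit-norm patch, scores
are invariant to the overall gain of the call — the detector responds to
the time-frequency *shape*, while the received level of each detection is
measured separately in dBFS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, find_peaks

from . import synth
from .signal import (SPECTROGRAM_PRESETS, AudioSegment, Selection, Spectrogram,
                     compute_spectrogram, selection_energy_dbfs)

__all__ = [
    "Template",
    "Detection",
    "build_templates",
    "default_templates",
    "correlation_track",
    "detect_d_calls",
    "merge_annotations",
    "tabulate_calls",
    "detections_to_frame",
]

#: Template band. The floor sits above the 17-24 Hz song band so that song
#: chorus energy cannot corrupt the correlation patch; every shipped sweep
#: variant still traverses most of the band.
DEFAULT_BAND_HZ = (30.0, 105.0)


@dataclass
class Template:
    """Normalized spectrogram patch for one exemplar call.

    ``patch`` is zero-mean and unit-norm when flattened, so correlating it
    against a patch of itself gives exactly 1.
    """

    patch: np.ndarray
    band_hz: tuple[float, float]
    duration_s: float
    id: str


@dataclass
class Detection:
    """One putative D call."""

    start_s: float
    end_s: float
    f_low_hz: float
    f_high_hz: float
    score: float
    best_template_id: str
    rl_dbfs: float
    source: str = "auto"

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


def _normalize_patch(patch: np.ndarray) -> np.ndarray:
    p = patch - patch.mean()
    nrm = np.linalg.norm(p)
    if nrm == 0:
        raise ValueError("exemplar patch has zero variance")
    return p / nrm


def build_templates(exemplars: list[AudioSegment],
                    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
                    ids: list[str] | None = None) -> list[Template]:
    """Convert exemplar waveforms into normalized spectrogram templates.

    Each exemplar is transformed with the ``detection`` preset, cropped to
    ``band_hz``, and normalized to zero mean / unit norm, which makes the
    match score invariant to exemplar gain.
    """
    if not exemplars:
        raise ValueError("need at least one exemplar")
    templates = []
    for i, ex in enumerate(exemplars):
        spec = compute_spectrogram(ex, **SPECTROGRAM_PRESETS["detection"])
        rows = spec.freq_slice(*band_hz)
        patch = _normalize_patch(spec.power[rows, :])
        tid = ids[i] if ids is not None else f"tpl{i:02d}"
        templates.append(Template(patch=patch, band_hz=band_hz,
                                  duration_s=ex.duration_s, id=tid))
    return templates


def default_templates(sample_rate_hz: float = 2000.0) -> list[Template]:
    """The shipped 13-template library.

    Twelve log-sweep exemplars covering durations {1.5, 2, 2.5, 3} s x
    sweep ranges {100->20, 90->25, 80->30} Hz, plus one curvilinear
    (fast-early) 100->20 Hz sweep, capturing the variability of natural
    D calls.
    """
    exemplars, ids = [], []
    for dur in (1.5, 2.0, 2.5, 3.0):
        for f0, f1 in ((100.0, 20.0), (90.0, 25.0), (80.0, 30.0)):
            exemplars.append(synth.gen_d_call(dur, f0, f1, amplitude=0.5,
                                              sample_rate_hz=sample_rate_hz))
            ids.append(f"sweep_{dur:g}s_{f0:g}-{f1:g}")
    exemplars.append(synth.gen_d_call(2.0, 100.0, 20.0, amplitude=0.5,
                                      sample_rate_hz=sample_rate_hz, curvature=1.0))
    ids.append("curvilinear_2s_100-20")
    return build_templates(exemplars, ids=ids)


def correlation_track(spectrogram: Spectrogram, template: Template) -> np.ndarray:
    """Normalized correlation score at every time lag.

    Lag ``l`` aligns the template's first frame with spectrogram column
    ``l``; the returned array has ``n_time - width + 1`` entries, each in
    [-1, 1]. A constant (zero-variance) spectrogram patch scores 0.
    """
    rows = spectrogram.freq_slice(*template.band_hz)
    S = spectrogram.power[rows, :]
    T = template.patch
    if S.shape[0] != T.shape[0]:
        raise ValueError("spectrogram band does not match the template band "
                         f"({S.shape[0]} vs {T.shape[0]} bins); use the same "
                         "preset and sample rate")
    w = T.shape[1]
    if S.shape[1] < w:
        raise ValueError("spectrogram shorter than the template")
    m = T.size
    # Pearson r against the zero-mean unit-norm template reduces to
    # <T, S_patch> / ||S_patch - mean|| at each lag; both terms are sliding sums.
    num = fftconvolve(S, T[::-1, ::-1], mode="valid")[0]
    ones = np.ones_like(T)
    s1 = fftconvolve(S, ones, mode="valid")[0]
    s2 = fftconvolve(S ** 2, ones, mode="valid")[0]
    var = np.maximum(s2 - s1 ** 2 / m, 0.0)
    denom = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(denom > 0, num / denom, 0.0)
    return np.clip(score, -1.0, 1.0)


def detect_d_calls(audio: AudioSegment, templates: list[Template] | None = None,
                   threshold: float = 0.80, min_gap_s: float = 1.0,
                   spectrogram: Spectrogram | None = None) -> list[Detection]:
    """Run the multi-template detector over a recording.

    The per-lag score is the max over templates; contiguous supra-threshold
    regions are collapsed to local maxima at least ``min_gap_s`` apart.
    Each detection carries the winning template's time/frequency extent,
    its score, and the received level over its selection box.
    """
    if templates is None:
        templates = default_templates(audio.sample_rate_hz)
    spec = spectrogram if spectrogram is not None else compute_spectrogram(
        audio, **SPECTROGRAM_PRESETS["detection"])

    n_time = spec.power.shape[1]
    widths = [t.patch.shape[1] for t in templates]
    n_lags = n_time - min(widths) + 1
    if n_lags < 1:
        raise ValueError("audio shorter than every template")
    best_score = np.full(n_lags, -np.inf)
    best_tpl = np.zeros(n_lags, dtype=int)
    for ti, tpl in enumerate(templates):
        if spec.power.shape[1] < tpl.patch.shape[1]:
            continue
        track = correlation_track(spec, tpl)
        upd = track > best_score[: track.size]
        best_score[: track.size][upd] = track[upd]
        best_tpl[: track.size][upd] = ti

    hop_s = spec.hop_s
    distance = max(1, int(round(min_gap_s / hop_s)))
    peaks, _ = find_peaks(best_score, height=threshold, distance=distance)
    # a supra-threshold plateau/run at either edge has no interior peak;
    # recover it as its maximum if no nearby peak already covers it
    if peaks.size == 0 and (best_score >= threshold).any():
        peaks = np.array([int(np.argmax(best_score))])

    frame_half = spec.params["n_fft"] / (2.0 * spec.params["sample_rate_hz"])
    detections = []
    for lag in peaks:
        tpl = templates[best_tpl[lag]]
        start = spec.times_s[lag] - frame_half
        det_box = Selection(start, start + tpl.duration_s, *tpl.band_hz)
        rl = selection_energy_dbfs(spec, det_box)
        detections.append(Detection(
            start_s=start, end_s=start + tpl.duration_s,
            f_low_hz=tpl.band_hz[0], f_high_hz=tpl.band_hz[1],
            score=float(best_score[lag]), best_template_id=tpl.id,
            rl_dbfs=rl, source="auto"))
    return detections


def merge_annotations(auto: list[Detection], removals: list[int] | None = None,
                      additions: list[Detection] | None = None) -> list[Detection]:
    """Apply a manual-review pass: drop false positives, add missed calls.

    ``removals`` are indices into ``auto``; ``additions`` are flagged
    ``source='manual'``. An addition overlapping an existing detection by
    more than 50% of its span triggers a warning but is kept — that is the
    reviewer's call to make.
    """
    removals = removals or []
    additions = additions or []
    bad = [i for i in removals if not 0 <= i < len(auto)]
    if bad:
        raise IndexError(f"removal indices out of range: {bad}")
    kept = [d for i, d in enumerate(auto) if i not in set(removals)]
    merged = list(kept)
    for add in additions:
        for d in kept:
            ov = min(add.end_s, d.end_s) - max(add.start_s, d.start_s)
            if ov > 0.5 * (add.end_s - add.start_s):
                warnings.warn(f"manual addition at {add.start_s:.2f}s overlaps an "
                              "existing detection by >50%; keeping both")
                break
        merged.append(replace(add, source="manual"))
    return sorted(merged, key=lambda d: d.start_s)


def tabulate_calls(detections: list[Detection],
                   window: tuple[float, float]) -> dict:
    """Count calls and average their received level inside a window.

    Membership is decided by the detection midpoint on the half-open
    interval [start, end). Mean RL averages the dB values directly; with
    zero calls it is NaN.
    """
    start, end = window
    if not start < end:
        raise ValueError("window must be ordered")
    inside = [d for d in detections if start <= d.midpoint_s < end]
    rls = [d.rl_dbfs for d in inside if np.isfinite(d.rl_dbfs)]
    return {"n_calls": len(inside),
            "mean_rl_dbfs": float(np.mean(rls)) if rls else float("nan")}


def detections_to_frame(detections: list[Detection]) -> pd.DataFrame:
    """Detections as a DataFrame ready for CSV / Raven selection-table export."""
    return pd.DataFrame([{
        "start_s": d.start_s, "end_s": d.end_s,
        "f_low_hz": d.f_low_hz, "f_high_hz": d.f_high_hz,
        "score": d.score, "best_template_id": d.best_template_id,
        "rl_dbfs": d.rl_dbfs, "source": d.source,
    } for d in detections])
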