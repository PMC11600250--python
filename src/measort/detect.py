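"""Spike detection and preprocessing for extracellular recordings.

Pipeline: zero-phase bandpass filtering (300–3000 Hz default), robust
noise estimation σ_m = median(|x|)/0.6745, amplitude thresholding at
−5σ_m (negative-deflection convention), 64-sample window extraction with
trough alignment, and conversion of each window to a 63-point
normalized-gradient feature vector — the representation fed to the
clustering-based sorters in :mod:`measort.sort`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .simulate import RawRecording

__all__ = [
    "FilteredRecording",
    "SpikeEvent",
    "SpikeWaveform",
    "PreprocessResult",
    "bandpass_filter",
    "estimate_noise",
    "detect_spikes",
    "extract_waveforms",
    "preprocess_spikes",
    "detect_and_preprocess",
    "WINDOW_LENGTH",
    "TROUGH_OFFSET",
]

#: Samples per extracted spike window and the fixed trough position inside it.
WINDOW_LENGTH = 64
TROUGH_OFFSET = 20


@dataclass
class FilteredRecording:
    samples: np.ndarray
    band: tuple[float, float]
    sampling_rate: float


@dataclass
class SpikeEvent:
    """One threshold crossing and the trough sample it leads to."""

    threshold_index: int
    trough_index: int
    channel_id: str = "sim"


@dataclass
class SpikeWaveform:
    """A 64-sample spike snippet with its minimum at ``trough_offset``."""

    samples: np.ndarray
    trough_offset: int = TROUGH_OFFSET


@dataclass
class PreprocessResult:
    """Feature matrix plus bookkeeping of rejected waveforms."""

    features: np.ndarray  # (n_kept, 63) gradients in 1/s of the unit-scaled shape
    kept_indices: np.ndarray  # indices into the input waveform list
    rejected: list[tuple[int, str]]  # (input index, reason)


def bandpass_filter(
    raw: RawRecording, low: float = 300.0, high: float = 3000.0
) -> FilteredRecording:
    """Zero-phase 4th-order Butterworth bandpass.

    Forward–backward filtering preserves spike shapes (no phase
    distortion).  Band edges must satisfy 0 < low < high < Nyquist.
    """
    nyq = raw.sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    sos = sps.butter(4, [low, high], btype="bandpass", fs=raw.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, np.asarray(raw.samples, dtype=float))
    return FilteredRecording(
        samples=filtered, band=(low, high), sampling_rate=raw.sampling_rate
    )


def estimate_noise(filtered: FilteredRecording | np.ndarray) -> float:
    """Robust background-noise scale σ_m = median(|x|) / 0.6745.

    0.6745 is the median of |Z| for standard-normal Z, so for Gaussian
    noise σ_m estimates the standard deviation while staying insensitive
    to the sparse, large-amplitude spike fraction of the trace.
    """
    x = filtered.samples if isinstance(filtered, FilteredRecording) else np.asarray(filtered)
    if x.size == 0:
        raise ValueError("cannot estimate noise of an empty signal")
    return float(np.median(np.abs(x)) / 0.6745)


def detect_spikes(
    filtered: FilteredRecording,
    sigma_m: float,
    multiplier: float = 5.0,
    dead_time: float = 0.0015,
) -> list[SpikeEvent]:
    """Find negative threshold crossings below −multiplier·σ_m.

    A spike event is the first sample where the signal drops below the
    threshold; further crossings within ``dead_time`` seconds are
    suppressed so one spike's multiple sub-threshold dips count once.
    The trough index is the minimum inside the 44 samples following the
    crossing.  Events too close to either edge for a full 64-sample
    window (20 before / 44 after) are dropped.
    """
    if multiplier < 0:
        raise ValueError("multiplier must be >= 0")
    if sigma_m < 0:
        raise ValueError("sigma_m must be >= 0")
    x = filtered.samples
    n = len(x)
    thr = -multiplier * sigma_m
    below = x < thr
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    if below.size and below[0]:
        crossings = np.concatenate([[0], crossings])
    dead = int(round(dead_time * filtered.sampling_rate))
    events: list[SpikeEvent] = []
    last = -np.inf
    pre, post = TROUGH_OFFSET, WINDOW_LENGTH - TROUGH_OFFSET
    for i in crossings:
        if i - last < dead:
            continue
        last = i
        if i < pre or i + post > n:
            continue  # no room for a full provisional window
        trough = i + int(np.argmin(x[i : i + post]))
        events.append(
            SpikeEvent(threshold_index=int(i), trough_index=int(trough), channel_id="sim")
        )
    return events


def extract_waveforms(
    filtered: FilteredRecording,
    events: list[SpikeEvent],
    pre_points: int = 20,
    post_points: int = 44,
) -> tuple[list[SpikeWaveform], list[SpikeEvent]]:
    """Cut trough-aligned 64-sample windows around each event.

    For each event the provisional window (``pre_points`` before the
    threshold crossing, ``post_points`` after) is cut, its minimum
    located, and the final window re-cut as 20 samples before the trough
    through 43 after it — so every waveform has length 64 with its
    minimum at position 20, as the clustering stage requires.  Events
    whose re-cut window would leave the recording are discarded.

    Returns
    -------
    (waveforms, kept_events)
        Parallel lists; ``kept_events`` maps each waveform back to its
        detection for downstream ground-truth matching.
    """
    if pre_points + post_points != WINDOW_LENGTH:
        raise ValueError("pre_points + post_points must equal 64")
    x = filtered.samples
    n = len(x)
    waveforms: list[SpikeWaveform] = []
    kept: list[SpikeEvent] = []
    for ev in events:
        i = ev.threshold_index
        if i - pre_points < 0 or i + post_points > n:
            continue
        window = x[i - pre_points : i + post_points]
        trough = i - pre_points + int(np.argmin(window))
        # iterate the re-cut until the window minimum sits at the trough
        # position: a re-cut window can expose a deeper sample outside
        # the provisional window (noise dip or neighbouring spike)
        ok = False
        for _ in range(8):
            start = trough - TROUGH_OFFSET
            stop = start + WINDOW_LENGTH
            if start < 0 or stop > n:
                break
            new_trough = start + int(np.argmin(x[start:stop]))
            if new_trough == trough:
                ok = True
                break
            trough = new_trough
        if not ok:
            continue
        w = x[start:stop].copy()
        waveforms.append(SpikeWaveform(samples=w, trough_offset=TROUGH_OFFSET))
        kept.append(SpikeEvent(ev.threshold_index, int(trough), ev.channel_id))
    return waveforms, kept


def preprocess_spikes(
    waveforms: list[SpikeWaveform], sampling_rate: float
) -> PreprocessResult:
    """Min-max normalize each waveform to [0, 1], then take its gradient.

    The gradient is the first difference divided by the sampling step
    Δt = 1/sampling_rate (50 µs at 20 kHz), giving a 63-value feature
    vector per spike.  Normalization first makes the features invariant
    to offset and gain; the gradient emphasises shape over level.
    Constant waveforms (max = min) are rejected with a reason.
    """
    dt = 1.0 / sampling_rate
    feats = []
    kept = []
    rejected: list[tuple[int, str]] = []
    for idx, wf in enumerate(waveforms):
        w = np.asarray(wf.samples, dtype=float)
        lo, hi = w.min(), w.max()
        if hi == lo:
            rejected.append((idx, "constant waveform: min-max scale undefined"))
            continue
        scaled = (w - lo) / (hi - lo)
        feats.append(np.diff(scaled) / dt)
        kept.append(idx)
    features = (
        np.vstack(feats) if feats else np.empty((0, WINDOW_LENGTH - 1))
    )
    return PreprocessResult(
        features=features,
        kept_indices=np.asarray(kept, dtype=np.int64),
        rejected=rejected,
    )


def detect_and_preprocess(
    raw: RawRecording,
    band: tuple[float, float] = (300.0, 3000.0),
    multiplier: float = 5.0,
    dead_time: float = 0.0015,
) -> tuple[np.ndarray, list[SpikeEvent]]:
    """Full front end: filter → threshold → extract → gradient features.

    Returns the (n, 63) feature matrix and the parallel list of detected
    events that survived windowing and preprocessing.
    """
    filtered = bandpass_filter(raw, *band)
    sigma = estimate_noise(filtered)
    events = detect_spikes(filtered, sigma, multiplier=multiplier, dead_time=dead_time)
    waveforms, kept_events = extract_waveforms(filtered, events)
    prep = preprocess_spikes(waveforms, raw.sampling_rate)
    events_out = [kept_events[i] for i in prep.kept_indices]
    return prep.features, events_out
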