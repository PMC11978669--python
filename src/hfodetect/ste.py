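"""Initial candidate screening by short-time energy (STE) thresholding.

The detector is deliberately tuned sensitivity-first: it must pass every real
HFO through to the clustering stage, accepting spikes, artifacts and the odd
background excursion as candidates ("pHFOs") to be sorted out later.

Frames are non-overlapping windows of ``frame_ms`` (10 ms); the frame energy
is the mean of squared samples.  A candidate is declared wherever at least
``min_consecutive`` (3) consecutive frames exceed the adaptive threshold
E0 = Eav + k * SD, and its centre is the midpoint of the first three frames
of the run.  The threshold statistics are computed on the frame-energy series
with the top ``trim_fraction`` of frames excluded, so that the events
themselves do not inflate the spread and mask shorter bursts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import SEGMENT_MS, IEEGRecording, preprocess_channel

DEFAULT_K = 5.0
FRAME_MS = 10.0
MIN_CONSECUTIVE = 3
TRIM_FRACTION = 0.02


@dataclass
class STETrace:
    """Per-frame short-time energies of one channel."""

    energies: np.ndarray
    frame_len_samples: int
    hop_samples: int
    fs_hz: float


@dataclass
class CandidateEvent:
    """A suspected HFO: 150 ms of raw signal centred on the detection."""

    channel: int
    center_sample: int
    raw_window: np.ndarray
    filtered_window: np.ndarray
    fs_hz: float
    peak_ste: float = 0.0
    true_kind: str | None = None


def frame_length(fs: float, frame_ms: float = FRAME_MS) -> int:
    """Frame size in samples; ceiling convention (26 samples at 2,560 Hz)."""
    return int(np.ceil(frame_ms * fs / 1000.0))


def short_time_energy(x: np.ndarray, fs: float, frame_ms: float = FRAME_MS) -> STETrace:
    """Mean squared amplitude per non-overlapping frame."""
    x = np.asarray(x, dtype=float)
    n = frame_length(fs, frame_ms)
    if x.size < n:
        raise ValueError(f"signal shorter than one frame ({x.size} < {n})")
    n_frames = x.size // n
    frames = x[:n_frames * n].reshape(n_frames, n)
    energies = np.mean(frames ** 2, axis=1)
    return STETrace(energies=energies, frame_len_samples=n, hop_samples=n, fs_hz=fs)


def ste_threshold(trace: STETrace, k: float = DEFAULT_K) -> float:
    """E0 = mean + k * population SD of the frame-energy series."""
    e = np.asarray(trace.energies, dtype=float)
    if e.size == 0:
        raise ValueError("empty STE trace")
    return float(np.mean(e) + k * np.std(e, ddof=0))


def _trimmed_threshold(trace: STETrace, k: float, trim_fraction: float) -> float:
    e = np.asarray(trace.energies, dtype=float)
    if trim_fraction > 0 and e.size > 10:
        cut = np.quantile(e, 1.0 - trim_fraction)
        kept = e[e <= cut]
        if kept.size:
            trimmed = STETrace(kept, trace.frame_len_samples, trace.hop_samples,
                               trace.fs_hz)
            return ste_threshold(trimmed, k)
    return ste_threshold(trace, k)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, length)."""
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(mask) - start))
    return runs


def detect_candidates(x_filtered: np.ndarray, x_raw: np.ndarray, fs: float,
                      k: float = DEFAULT_K, frame_ms: float = FRAME_MS,
                      min_consecutive: int = MIN_CONSECUTIVE,
                      trim_fraction: float = TRIM_FRACTION,
                      channel: int = 0) -> list[CandidateEvent]:
    """Scan one channel's STE trace for runs of supra-threshold frames.

    Each maximal run of >= ``min_consecutive`` frames yields one candidate
    centred at the midpoint of the run's first three frames; the 150 ms
    windows are cut from the *raw* and the band-passed signal.  Candidates
    closer than one window are merged, keeping the higher-energy one.
    """
    x_filtered = np.asarray(x_filtered, dtype=float)
    x_raw = np.asarray(x_raw, dtype=float)
    if x_filtered.shape != x_raw.shape:
        raise ValueError("filtered and raw signals must be aligned and equal length")
    n = frame_length(fs, frame_ms)
    if x_filtered.size < n:
        return []
    trace = short_time_energy(x_filtered, fs, frame_ms)
    e0 = _trimmed_threshold(trace, k, trim_fraction)
    mask = trace.energies > e0
    w = int(round(SEGMENT_MS * fs / 1000.0))
    cands: list[CandidateEvent] = []
    for start, length in _runs_above(mask):
        if length < min_consecutive:
            continue
        center = int(round((start + min_consecutive / 2.0) * n))
        s = int(np.clip(center - w // 2, 0, max(x_raw.size - w, 0)))
        if x_raw.size < w:
            continue
        peak = float(np.max(trace.energies[start:start + length]))
        cands.append(CandidateEvent(channel=channel, center_sample=center,
                                    raw_window=x_raw[s:s + w].copy(),
                                    filtered_window=x_filtered[s:s + w].copy(),
                                    fs_hz=fs, peak_ste=peak))
    # merge near-duplicates (closer than one analysis window)
    merged: list[CandidateEvent] = []
    for c in cands:
        if merged and abs(c.center_sample - merged[-1].center_sample) < w:
            if c.peak_ste > merged[-1].peak_ste:
                merged[-1] = c
        else:
            merged.append(c)
    return merged


def detect_recording(rec: IEEGRecording, k: float = DEFAULT_K,
                     frame_ms: float = FRAME_MS,
                     min_consecutive: int = MIN_CONSECUTIVE,
                     trim_fraction: float = TRIM_FRACTION,
                     filter_mode: str = "continuous") -> list[CandidateEvent]:
    """Filter every channel and run candidate detection on each."""
    out: list[CandidateEvent] = []
    for ch in range(rec.n_channels):
        raw = rec.samples[ch]
        filt = preprocess_channel(raw, rec.fs_hz, mode=filter_mode)
        out.extend(detect_candidates(filt, raw, rec.fs_hz, k=k, frame_ms=frame_ms,
                                     min_consecutive=min_consecutive,
                                     trim_fraction=trim_fraction, channel=ch))
    return out
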