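"""Synthetic iEEG with ground-truth events for validating the HFO detector.

Clinical iEEG corpora with expert HFO annotations are rarely shareable, so
every downstream stage is exercised on simulated recordings instead: pink
(1/f) background noise with 50 Hz line interference, into which four event
classes are injected with known positions:

* ripples            -- Gaussian-windowed sinusoids, 80-250 Hz
* fast ripples       -- Gaussian-windowed sinusoids, 250-500 Hz
* interictal spikes  -- sharp biphasic transients (exponential cusp + slow
                        after-wave) whose band-pass ringing mimics the classic
                        false-HFO mechanism
* artifacts          -- EMG/movement-like band-limited noise bursts

Event amplitudes are calibrated against the background RMS *in the 80-500 Hz
detection band*, so a stated SNR directly controls detectability.  All output
is a pure function of the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import IEEGRecording, bandpass_filter

KINDS = ("ripple", "fast_ripple", "spike", "artifact")
OSCILLATORY = ("ripple", "fast_ripple")

RIPPLE_BAND = (80.0, 250.0)
FAST_RIPPLE_BAND = (250.0, 500.0)

# Realistic per-class draws (no clinical statistics exist to copy; see
# docs/methods.md).  Oscillatory durations are chosen so the supra-threshold
# part of the Gaussian envelope spans >= 3 consecutive 10 ms detector frames
# at *any* frame alignment (span ~ 4.5 sigma ~ 0.75 * duration >= 50 ms).
RIPPLE_FREQ = (160.0, 25.0, 100.0, 240.0)        # mean, sd, clip lo, clip hi
FAST_RIPPLE_FREQ = (350.0, 45.0, 260.0, 480.0)
DURATION_MS = {
    "ripple": (70.0, 100.0),
    "fast_ripple": (70.0, 90.0),
    "spike": (60.0, 90.0),
    "artifact": (60.0, 90.0),
}
ARTIFACT_BAND = (20.0, 90.0)  # EMG/movement burst: sub-HFO-band dominant


@dataclass
class EventSpec:
    """One event to inject: kind, position, morphology parameters."""

    kind: str
    center_s: float
    duration_ms: float
    amplitude: float
    channel: int
    freq_hz: float | None = None  # oscillatory kinds only

    def validate(self, rec: IEEGRecording) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        half = self.duration_ms / 2000.0
        if self.center_s - half < 0 or self.center_s + half > rec.duration_s:
            raise ValueError("event outside recording bounds")
        if not 0 <= self.channel < rec.n_channels:
            raise ValueError("channel index out of range")
        if self.kind == "ripple":
            if self.freq_hz is None or not (RIPPLE_BAND[0] <= self.freq_hz < RIPPLE_BAND[1]):
                raise ValueError("ripple freq_hz must lie in [80, 250)")
        if self.kind == "fast_ripple":
            if self.freq_hz is None or not (FAST_RIPPLE_BAND[0] <= self.freq_hz <= FAST_RIPPLE_BAND[1]):
                raise ValueError("fast_ripple freq_hz must lie in [250, 500]")


def _default_rates() -> dict[str, float]:
    return {"ripple": 9.0, "fast_ripple": 9.0, "spike": 18.0, "artifact": 10.0}


def _default_snr() -> dict[str, float]:
    return {k: 20.0 for k in KINDS}


@dataclass
class SynthConfig:
    """Benchmark recording conditions.  ``seed`` fully determines the output."""

    n_channels: int = 4
    duration_s: float = 600.0
    fs_hz: float = 2560.0
    background_scale: float = 10.0   # microvolt RMS of the pink background
    line_noise_amp: float = 5.0      # 50 Hz sinusoid amplitude, microvolts
    event_rates: dict[str, float] = field(default_factory=_default_rates)
    snr_db: dict[str, float] = field(default_factory=_default_snr)
    min_spacing_s: float = 0.3       # per-channel spacing: one event per window
    seed: int = 42

    def validate(self) -> None:
        if self.fs_hz < 1000:
            raise ValueError("fs_hz must be >= 1000 so Nyquist covers 500 Hz")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.n_channels <= 0:
            raise ValueError("n_channels must be positive")


def generate_background(config: SynthConfig) -> IEEGRecording:
    """Pink (1/f power) noise per channel plus an additive 50 Hz sinusoid."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs_hz))
    out = np.zeros((config.n_channels, n))
    freqs = np.fft.rfftfreq(n, d=1.0 / config.fs_hz)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])  # amplitude ~ f^-1/2 -> power ~ 1/f
    t = np.arange(n) / config.fs_hz
    for ch in range(config.n_channels):
        white = rng.standard_normal(n)
        phase = rng.uniform(0, 2 * np.pi)
        if config.background_scale > 0:
            pink = np.fft.irfft(np.fft.rfft(white) * shaping, n=n)
            rms = np.sqrt(np.mean(pink ** 2))
            out[ch] = pink * (config.background_scale / rms)
        if config.line_noise_amp > 0:
            out[ch] += config.line_noise_amp * np.sin(2 * np.pi * 50.0 * t + phase)
    return IEEGRecording(out, config.fs_hz)


def _event_rng(rng_seed: int, ev: EventSpec, fs: float) -> np.random.Generator:
    # Per-event generator keyed on (seed, position): the same event produces
    # the same waveform whether built during SNR calibration or injection.
    center = int(round(ev.center_s * fs))
    return np.random.default_rng(
        np.random.SeedSequence([int(rng_seed), ev.channel, center, KINDS.index(ev.kind)])
    )


def event_waveform(ev: EventSpec, fs: float, rng_seed: int = 0) -> np.ndarray:
    """Unit-peak waveform of one event on its support grid (len = duration)."""
    n = max(3, int(round(ev.duration_ms * fs / 1000.0)))
    t = (np.arange(n) - (n - 1) / 2) / fs
    sigma = ev.duration_ms / 6000.0  # Gaussian envelope, sigma = duration/6
    rng = _event_rng(rng_seed, ev, fs)
    if ev.kind in OSCILLATORY:
        phase = rng.uniform(0, 2 * np.pi)
        w = np.exp(-t ** 2 / (2 * sigma ** 2)) * np.sin(2 * np.pi * ev.freq_hz * t + phase)
    elif ev.kind == "spike":
        tau = ev.duration_ms / 14000.0  # ~4-6 ms cusp
        cusp = np.exp(-np.abs(t) / tau)
        wave_c = 0.35 * ev.duration_ms / 1000.0
        wave_s = 0.15 * ev.duration_ms / 1000.0
        w = cusp - 0.45 * np.exp(-((t - wave_c) ** 2) / (2 * wave_s ** 2))
    elif ev.kind == "artifact":
        noise = rng.standard_normal(n)
        if fs / 2 > ARTIFACT_BAND[1]:
            pad = n  # reflect-free zero pad keeps the burst finite-support
            noise = bandpass_filter(np.concatenate([np.zeros(pad), noise, np.zeros(pad)]),
                                    fs, band=ARTIFACT_BAND)[pad:pad + n]
        w = noise * np.exp(-t ** 2 / (2 * sigma ** 2))
    else:  # pragma: no cover - guarded by validate()
        raise ValueError(ev.kind)
    peak = np.max(np.abs(w))
    return w / peak if peak > 0 else w


def inject_events(rec: IEEGRecording, events: list[EventSpec],
                  rng_seed: int = 0) -> tuple[IEEGRecording, pd.DataFrame]:
    """Add events to a recording; returns the new recording plus annotations.

    Annotations (channel, center_sample, kind, freq_hz, duration_ms, amplitude)
    are sorted by (channel, center_sample).  Out-of-bounds or invalid events
    raise with the offending event index.
    """
    out = rec.samples.copy()
    rows = []
    for i, ev in enumerate(events):
        try:
            ev.validate(rec)
        except ValueError as exc:
            raise ValueError(f"event {i}: {exc}") from exc
        w = event_waveform(ev, rec.fs_hz, rng_seed) * ev.amplitude
        center = int(round(ev.center_s * rec.fs_hz))
        start = center - len(w) // 2
        if start < 0 or start + len(w) > rec.n_samples:
            raise ValueError(f"event {i}: support extends outside the recording")
        out[ev.channel, start:start + len(w)] += w
        rows.append({"channel": ev.channel, "center_sample": center, "kind": ev.kind,
                     "freq_hz": ev.freq_hz, "duration_ms": ev.duration_ms,
                     "amplitude": ev.amplitude})
    ann = pd.DataFrame(rows, columns=["channel", "center_sample", "kind",
                                      "freq_hz", "duration_ms", "amplitude"])
    ann = ann.sort_values(["channel", "center_sample"], kind="mergesort").reset_index(drop=True)
    return IEEGRecording(out, rec.fs_hz, list(rec.channel_labels)), ann


def _band_rms(x: np.ndarray, fs: float) -> float:
    return float(np.sqrt(np.mean(bandpass_filter(x, fs) ** 2)))


def _unit_band_rms(ev: EventSpec, fs: float, rng_seed: int) -> float:
    """RMS of the unit-peak waveform in the 80-500 Hz band, over its support."""
    w = event_waveform(ev, fs, rng_seed)
    pad = len(w)
    filt = bandpass_filter(np.concatenate([np.zeros(pad), w, np.zeros(pad)]), fs)
    return float(np.sqrt(np.mean(filt[pad:pad + len(w)] ** 2)))


def draw_events(config: SynthConfig, rng: np.random.Generator,
                n_channels: int) -> list[EventSpec]:
    """Poisson event placement honouring the per-channel minimum spacing."""
    duration_min = config.duration_s / 60.0
    placed: dict[int, list[float]] = {ch: [] for ch in range(n_channels)}
    events: list[EventSpec] = []
    margin = 0.2
    for kind in KINDS:
        rate = config.event_rates.get(kind, 0.0)
        count = rng.poisson(rate * duration_min) if rate > 0 else 0
        for _ in range(count):
            for _attempt in range(1000):
                ch = int(rng.integers(n_channels))
                c = float(rng.uniform(margin, config.duration_s - margin))
                if all(abs(c - o) >= config.min_spacing_s for o in placed[ch]):
                    placed[ch].append(c)
                    break
            else:  # pragma: no cover - only at implausible densities
                continue
            dur = float(rng.uniform(*DURATION_MS[kind]))
            freq = None
            if kind == "ripple":
                m, s, lo, hi = RIPPLE_FREQ
                freq = float(np.clip(rng.normal(m, s), lo, hi))
            elif kind == "fast_ripple":
                m, s, lo, hi = FAST_RIPPLE_FREQ
                freq = float(np.clip(rng.normal(m, s), lo, hi))
            events.append(EventSpec(kind=kind, center_s=c, duration_ms=dur,
                                    amplitude=1.0, channel=ch, freq_hz=freq))
    return events


def make_benchmark(config: SynthConfig) -> tuple[IEEGRecording, pd.DataFrame]:
    """Background + Poisson-placed events with SNR-calibrated amplitudes.

    The amplitude of each event is set so that its RMS in the 80-500 Hz band,
    over the event support, is ``snr_db`` above the channel's band-limited
    background RMS.
    """
    config.validate()
    bg = generate_background(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    events = draw_events(config, rng, config.n_channels)
    wave_seed = config.seed + 1
    bg_rms = [_band_rms(bg.samples[ch], config.fs_hz) for ch in range(config.n_channels)]
    for ev in events:
        unit = _unit_band_rms(ev, config.fs_hz, wave_seed)
        target = 10.0 ** (config.snr_db.get(ev.kind, 20.0) / 20.0) * bg_rms[ev.channel]
        ev.amplitude = target / unit if unit > 0 else 0.0
    return inject_events(bg, events, rng_seed=wave_seed)
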