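"""Time-frequency imaging of candidate windows.

Each 150 ms candidate window is transformed with an analytic generalized
Morse continuous wavelet transform (gamma=3, beta=20, i.e. time-bandwidth
P^2 = 60), rendered as a blue-to-red colour raster of 875 x 656 pixels, and
reduced to its red channel resized to 64 x 64 (the "R-TFM").  Real HFOs show
up as an isolated island of red pixels inside their band, whereas spikes and
artifacts paint the low-frequency edge or a broadband smear -- the morphology
the downstream auto-encoder and clustering stages feed on.

The Morse wavelet is defined directly in the frequency domain,
``psi(w) ~ w^beta * exp(-w^gamma)`` for ``w > 0``, and applied by FFT
filtering; the window is zero-padded symmetrically to suppress wrap-around.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import LinearSegmentedColormap
from skimage.transform import resize

MORSE_GAMMA = 3.0
MORSE_BETA = 20.0
VOICES_PER_OCTAVE = 16
FREQ_RANGE = (60.0, 600.0)
RASTER_SHAPE = (875, 656)
RTFM_SHAPE = (64, 64)

# Blue -> cyan -> yellow -> red; the red channel rises monotonically with
# energy so that the red plane alone is a faithful energy surrogate.
ENERGY_CMAP = LinearSegmentedColormap.from_list(
    "energy_jet",
    [(0.0, (0.0, 0.0, 0.5)), (0.25, (0.0, 0.0, 1.0)), (0.5, (0.0, 1.0, 1.0)),
     (0.75, (1.0, 1.0, 0.0)), (1.0, (1.0, 0.0, 0.0))],
)


@dataclass
class TimeFrequencyMap:
    """CWT magnitudes on a log-frequency grid, plus the rendered raster."""

    magnitude: np.ndarray          # (freq x time), ascending frequency
    freqs_hz: np.ndarray
    times_s: np.ndarray
    rgb: np.ndarray | None = field(default=None, repr=False)


def morse_frequencies(fmin: float = FREQ_RANGE[0], fmax: float = FREQ_RANGE[1],
                      voices: int = VOICES_PER_OCTAVE) -> np.ndarray:
    n = int(np.floor(np.log2(fmax / fmin) * voices)) + 1
    return fmin * 2.0 ** (np.arange(n) / voices)


def cwt_morse(window: np.ndarray, fs: float, gamma: float = MORSE_GAMMA,
              beta: float = MORSE_BETA, voices: int = VOICES_PER_OCTAVE,
              freq_range: tuple[float, float] = FREQ_RANGE) -> TimeFrequencyMap:
    """Analytic Morse CWT magnitude of a candidate window."""
    x = np.asarray(window, dtype=float)
    if x.size < 64:
        raise ValueError("window too short for time-frequency analysis")
    if freq_range[1] > fs / 2:
        raise ValueError(f"sampling rate {fs} Hz cannot resolve {freq_range[1]} Hz")
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    off = (nfft - n) // 2
    xp = np.zeros(nfft)
    xp[off:off + n] = x
    xhat = np.fft.fft(xp)

    freqs = morse_frequencies(freq_range[0], freq_range[1], voices)
    omega = 2 * np.pi * np.arange(nfft) / nfft          # rad/sample, full circle
    omega_peak = (beta / gamma) ** (1.0 / gamma)
    scales = omega_peak * fs / (2 * np.pi * freqs)      # scale per centre frequency
    # log-domain evaluation, peak-normalised to 2 (analytic convention)
    somega = scales[:, None] * omega[None, :]
    with np.errstate(divide="ignore"):
        logpsi = beta * np.log(somega) - somega ** gamma
    logpeak = beta * np.log(omega_peak) - beta / gamma
    psi = 2.0 * np.exp(logpsi - logpeak)
    psi[:, 0] = 0.0
    half = nfft // 2
    psi[:, half + 1:] = 0.0                             # analytic: positive freqs only
    coeffs = np.fft.ifft(xhat[None, :] * psi, axis=1)[:, off:off + n]
    mag = np.abs(coeffs)
    times = np.arange(n) / fs
    return TimeFrequencyMap(magnitude=mag, freqs_hz=freqs, times_s=times)


def render_tfm(tf_map: TimeFrequencyMap,
               shape: tuple[int, int] = RASTER_SHAPE) -> np.ndarray:
    """Min-max normalise the magnitude and rasterise through the colormap.

    Returns a float RGB raster of exactly ``shape + (3,)`` with values in
    [0, 1].  An all-zero map renders at the colormap's low end; a non-zero
    constant map renders mid-colormap (no divide-by-zero).
    """
    mag = np.asarray(tf_map.magnitude, dtype=float)
    if mag.size == 0:
        raise ValueError("empty magnitude matrix")
    lo, hi = float(mag.min()), float(mag.max())
    if hi == lo:
        norm = np.zeros_like(mag) if hi == 0.0 else np.full_like(mag, 0.5)
    else:
        norm = (mag - lo) / (hi - lo)
    norm = resize(norm, shape, order=1, mode="edge", anti_aliasing=False)
    rgb = ENERGY_CMAP(norm)[..., :3]
    tf_map.rgb = rgb
    return rgb


def extract_rtfm(rgb: np.ndarray, shape: tuple[int, int] = RTFM_SHAPE) -> np.ndarray:
    """Red channel of the raster, rescaled to [0, 1] and area-resized to 64x64."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) raster")
    red = rgb[..., 0].astype(float)
    if rgb.dtype == np.uint8:
        red = red / 255.0
    small = resize(red, shape, order=1, mode="edge", anti_aliasing=True)
    return np.clip(small, 0.0, 1.0)


def window_to_rtfm(window: np.ndarray, fs: float, **cwt_kwargs) -> np.ndarray:
    """Full imaging chain for one candidate window: CWT -> raster -> R-TFM."""
    tf_map = cwt_morse(window, fs, **cwt_kwargs)
    rgb = render_tfm(tf_map)
    return extract_rtfm(rgb)


def windows_to_rtfms(windows: list[np.ndarray], fs: float, **cwt_kwargs) -> np.ndarray:
    """Stack of R-TFMs, shape (n, 64, 64)."""
    return np.stack([window_to_rtfm(w, fs, **cwt_kwargs) for w in windows])


def tfm_small(rgb: np.ndarray, shape: tuple[int, int] = RTFM_SHAPE) -> np.ndarray:
    """Full-colour raster resized to 64x64x3 (ablation feature set)."""
    return np.clip(resize(np.asarray(rgb, dtype=float), shape + (3,),
                          order=1, mode="edge", anti_aliasing=True), 0.0, 1.0)


def imaging_features(windows: list[np.ndarray], fs: float,
                     **cwt_kwargs) -> tuple[np.ndarray, np.ndarray]:
    """R-TFMs and downsized colour TFMs for a list of candidate windows.

    Computes the CWT and raster once per window; returns
    ``(rtfms (n,64,64), tfm64s (n,64,64,3))``.
    """
    rtfms, smalls = [], []
    for w in windows:
        tf_map = cwt_morse(w, fs, **cwt_kwargs)
        rgb = render_tfm(tf_map)
        rtfms.append(extract_rtfm(rgb))
        smalls.append(tfm_small(rgb))
    return np.stack(rtfms), np.stack(smalls)
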