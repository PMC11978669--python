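import numpy as np
import pytest

from hfodetect import ste, synth


@pytest.fixture(scope="session")
def mini_benchmark():
    """Small synthetic recording with ground truth, shared across test modules."""
    cfg = synth.SynthConfig(n_channels=2, duration_s=180.0, seed=7)
    rec, ann = synth.make_benchmark(cfg)
    return cfg, rec, ann


@pytest.fixture(scope="session")
def mini_candidates(mini_benchmark):
    _, rec, _ = mini_benchmark
    return ste.detect_recording(rec)


def blob_image(row: int, col: int, sigma: float = 6.0,
               noise: float = 0.0, seed: int = 0) -> np.ndarray:
    """A 64x64 image with a Gaussian blob: a cheap stand-in for an R-TFM island."""
    r, c = np.mgrid[0:64, 0:64]
    img = np.exp(-((r - row) ** 2 + (c - col) ** 2) / (2 * sigma ** 2))
    if noise > 0:
        rng = np.random.default_rng(seed)
        img = img + noise * rng.uniform(0, 1, img.shape)
    return np.clip(img, 0.0, 1.0)


@pytest.fixture(scope="session")
def two_class_images():
    """Two visually distinct synthetic image classes (40 of each)."""
    a = np.stack([blob_image(16, 16, noise=0.05, seed=i) for i in range(40)])
    b = np.stack([blob_image(48, 48, noise=0.05, seed=100 + i) for i in range(40)])
    labels = np.array([0] * 40 + [1] * 40)
    return np.concatenate([a, b]), labels
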