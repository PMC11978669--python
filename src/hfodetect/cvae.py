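"""Convolutional variational auto-encoder for denoising R-TFM images.

The model follows the classic CVAE recipe: an encoder of two stride-2
convolutions (64x64 -> 32x32 -> 16x16 feature maps, 3x3 kernels, 32 then 64
filters) feeding two linear heads for the posterior mean and log-variance; a
mirror decoder of a linear layer and two transposed convolutions back to a
64x64 sigmoid output.  Training minimises the negative ELBO: a per-pixel
Bernoulli cross-entropy reconstruction term plus the closed-form KL
divergence between the diagonal-Gaussian posterior and the unit-Gaussian
prior, optimised with Adam.  At inference the deterministic code z = mu is
decoded, so reconstructions are reproducible.

Everything is plain NumPy: convolutions via im2col/col2im, gradients by
hand.  The images are small (64x64) and the network shallow, so CPU training
on a few hundred maps takes seconds per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

IMG = 64
MAX_EPOCHS = 200


@dataclass
class CVAEConfig:
    latent_dim: int = 50
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    likelihood: str = "bernoulli"   # or "gaussian"
    dtype: str = "float32"

    def validate(self) -> None:
        if self.latent_dim <= 0:
            raise ValueError("latent_dim must be positive")
        if self.epochs > MAX_EPOCHS:
            raise ValueError(f"epochs capped at {MAX_EPOCHS}")
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if self.likelihood not in ("bernoulli", "gaussian"):
            raise ValueError("likelihood must be 'bernoulli' or 'gaussian'")


@dataclass
class LatentCode:
    """Posterior parameters and the sampled code for one image."""

    mu: np.ndarray
    log_sigma: np.ndarray
    z: np.ndarray


# ---------------------------------------------------------------------------
# im2col / col2im primitives (3x3 kernels, stride 2, pad 1 throughout)

def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    cols = np.empty((b, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
    return cols.reshape(b, c * k * k, oh * ow), (x.shape, oh, ow)


def _col2im(cols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int,
            oh: int, ow: int) -> np.ndarray:
    b, c, h, w = x_shape
    cols = cols.reshape(b, c, k, k, oh, ow)
    xp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += cols[:, :, i, j]
    return xp[:, :, pad:pad + h, pad:pad + w]


class _Conv:
    """Stride-2 3x3 convolution with bias."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype):
        fan_in = cin * 9
        self.w = (rng.standard_normal((cout, cin, 3, 3)) * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.cin, self.cout = cin, cout

    def forward(self, x):
        cols, (xshape, oh, ow) = _im2col(x, 3, 2, 1)
        wm = self.w.reshape(self.cout, -1)
        out = np.matmul(wm[None], cols) + self.b[None, :, None]
        self.cache = (cols, xshape, oh, ow)
        return out.reshape(x.shape[0], self.cout, oh, ow)

    def backward(self, dout):
        cols, xshape, oh, ow = self.cache
        b = dout.shape[0]
        dm = dout.reshape(b, self.cout, oh * ow)
        self.dw = np.matmul(dm, cols.transpose(0, 2, 1)).sum(0).reshape(self.w.shape)
        self.db = dm.sum(axis=(0, 2))
        wm = self.w.reshape(self.cout, -1)
        dcols = np.matmul(wm.T[None], dm)
        return _col2im(dcols, xshape, 3, 2, 1, oh, ow)

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class _ConvT:
    """Transpose of the stride-2 3x3 convolution (upsampling by 2)."""

    def __init__(self, cin: int, cout: int, out_hw: int, rng: np.random.Generator, dtype):
        fan_in = cin * 9
        self.w = (rng.standard_normal((cin, cout, 3, 3)) * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.cin, self.cout, self.out_hw = cin, cout, out_hw

    def forward(self, y):
        b, f, h, w = y.shape
        ym = y.reshape(b, f, h * w)
        wm = self.w.reshape(self.cin, -1)
        cols = np.matmul(wm.T[None], ym)
        out_shape = (b, self.cout, self.out_hw, self.out_hw)
        out = _col2im(cols, out_shape, 3, 2, 1, h, w) + self.b[None, :, None, None]
        self.cache = (ym, h, w, out_shape)
        return out

    def backward(self, dout):
        ym, h, w, out_shape = self.cache
        dcols, _ = _im2col(dout, 3, 2, 1)
        wm = self.w.reshape(self.cin, -1)
        dy = np.matmul(wm[None], dcols).reshape(ym.shape[0], self.cin, h, w)
        self.dw = np.matmul(ym, dcols.transpose(0, 2, 1)).sum(0).reshape(self.w.shape)
        self.db = dout.sum(axis=(0, 2, 3))
        return dy

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class _Linear:
    def __init__(self, nin: int, nout: int, rng: np.random.Generator, dtype, gain=1.0):
        self.w = (rng.standard_normal((nin, nout)) * gain / np.sqrt(nin)).astype(dtype)
        self.b = np.zeros(nout, dtype=dtype)

    def forward(self, x):
        self.cache = x
        return x @ self.w + self.b

    def backward(self, dout):
        x = self.cache
        self.dw = x.T @ dout
        self.db = dout.sum(0)
        return dout @ self.w.T

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def gaussian_kl(mu: np.ndarray, log_sigma: np.ndarray) -> np.ndarray:
    """Per-dimension KL( N(mu, sigma^2) || N(0, 1) ) in closed form."""
    mu = np.asarray(mu, dtype=float)
    log_sigma = np.asarray(log_sigma, dtype=float)
    return 0.5 * (mu ** 2 + np.exp(2 * log_sigma) - 1.0 - 2 * log_sigma)


def reparameterize(mu: np.ndarray, log_sigma: np.ndarray,
                   noise_seed: int | None = 0) -> np.ndarray:
    """z = mu + exp(log_sigma) * eps with eps ~ N(0, I) drawn from noise_seed."""
    mu = np.asarray(mu, dtype=float)
    log_sigma = np.asarray(log_sigma, dtype=float)
    if mu.shape != log_sigma.shape:
        raise ValueError("mu and log_sigma must have equal shape")
    eps = np.random.default_rng(noise_seed).standard_normal(mu.shape)
    return mu + np.exp(log_sigma) * eps


class CVAE:
    """Two-conv-layer variational auto-encoder over 64x64 images in [0, 1]."""

    def __init__(self, config: CVAEConfig):
        config.validate()
        self.config = config
        dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(config.seed)
        l = config.latent_dim
        self.conv1 = _Conv(1, 32, rng, dtype)
        self.conv2 = _Conv(32, 64, rng, dtype)
        self.fc_mu = _Linear(64 * 16 * 16, l, rng, dtype)
        self.fc_lv = _Linear(64 * 16 * 16, l, rng, dtype)
        self.fc_dec = _Linear(l, 64 * 16 * 16, rng, dtype, gain=np.sqrt(2.0))
        self.deconv1 = _ConvT(64, 32, 32, rng, dtype)
        self.deconv2 = _ConvT(32, 1, 64, rng, dtype)
        self.dtype = dtype
        self.trained = False
        self._adam: dict | None = None

    # -- forward pieces ----------------------------------------------------
    def _layers(self):
        return [self.conv1, self.conv2, self.fc_mu, self.fc_lv,
                self.fc_dec, self.deconv1, self.deconv2]

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (mu, logvar); ``x`` is (B, 64, 64) or (B, 1, 64, 64)."""
        x = self._as_batch(x)
        h1 = np.maximum(self.conv1.forward(x), 0)
        h2 = np.maximum(self.conv2.forward(h1), 0)
        f = h2.reshape(x.shape[0], -1)
        self._enc_cache = (x, h1, h2, f)
        return self.fc_mu.forward(f), self.fc_lv.forward(f)

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Decode latent codes to (B, 64, 64) images in [0, 1]."""
        z = np.asarray(z, dtype=self.dtype)
        if z.ndim == 1:
            z = z[None]
        logits = self._decode_logits(z)
        return _sigmoid(logits)[:, 0]

    def _decode_logits(self, z: np.ndarray) -> np.ndarray:
        d = self.fc_dec.forward(z)
        dr = np.maximum(d, 0)
        self._dec_cache_pre = d
        h = dr.reshape(z.shape[0], 64, 16, 16)
        d1 = self.deconv1.forward(h)
        d1r = np.maximum(d1, 0)
        self._dec_cache = (d1,)
        return self.deconv2.forward(d1r)

    def _as_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[1:] != (1, IMG, IMG):
            raise ValueError(f"expected (B, {IMG}, {IMG}) images, got {x.shape}")
        return x

    # -- loss and gradients -------------------------------------------------
    def loss_and_grads(self, x: np.ndarray, eps: np.ndarray | None,
                       want_grads: bool = True) -> tuple[float, float, float]:
        x = self._as_batch(x)
        b = x.shape[0]
        mu, lv = self.encode(x)
        if eps is None:
            z = mu
        else:
            z = mu + np.exp(0.5 * lv) * eps.astype(self.dtype)
        logits = self._decode_logits(z)
        t = x
        if self.config.likelihood == "bernoulli":
            # stable softplus form of -log p(x|z)
            rec = np.maximum(logits, 0) - logits * t + np.log1p(np.exp(-np.abs(logits)))
            rec_term = float(rec.sum()) / b
        else:
            y = _sigmoid(logits)
            rec_term = 0.5 * float(((y - t) ** 2).sum()) / b
        kl = 0.5 * (mu.astype(float) ** 2 + np.exp(lv.astype(float)) - 1.0 - lv.astype(float))
        kl_term = float(kl.sum()) / b
        loss = rec_term + kl_term
        if not want_grads:
            return loss, rec_term, kl_term

        if self.config.likelihood == "bernoulli":
            dlogits = (_sigmoid(logits) - t) / b
        else:
            y = _sigmoid(logits)
            dlogits = (y - t) * y * (1 - y) / b
        dd1r = self.deconv2.backward(dlogits.astype(self.dtype))
        (d1,) = self._dec_cache
        dd1 = dd1r * (d1 > 0)
        dh = self.deconv1.backward(dd1)
        ddec = dh.reshape(b, -1) * (self._dec_cache_pre > 0)
        dz = self.fc_dec.backward(ddec)
        dmu = dz + (mu / b).astype(self.dtype)
        dlv = 0.5 * (np.exp(lv) - 1.0) / b
        if eps is not None:
            dlv = dlv + dz * eps.astype(self.dtype) * 0.5 * np.exp(0.5 * lv)
        _, h1, h2, f = self._enc_cache
        df = self.fc_mu.backward(dmu.astype(self.dtype)) + self.fc_lv.backward(dlv.astype(self.dtype))
        dh2 = df.reshape(h2.shape) * (h2 > 0)
        dh1 = self.conv2.backward(dh2) * (h1 > 0)
        self.conv1.backward(dh1)
        return loss, rec_term, kl_term

    # -- optimisation --------------------------------------------------------
    def _adam_step(self, lr: float):
        if self._adam is None:
            self._adam = {"t": 0, "m": {}, "v": {}}
        st = self._adam
        st["t"] += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for li, layer in enumerate(self._layers()):
            for name, p, gname in layer.params():
                g = getattr(layer, gname).astype(p.dtype)
                key = (li, name)
                m = st["m"].get(key, np.zeros_like(p))
                v = st["v"].get(key, np.zeros_like(p))
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                st["m"][key], st["v"][key] = m, v
                mhat = m / (1 - b1 ** st["t"])
                vhat = v / (1 - b2 ** st["t"])
                p -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(p.dtype)


def build_model(config: CVAEConfig) -> CVAE:
    """Seed-deterministic model construction."""
    return CVAE(config)


def elbo_loss(batch: np.ndarray, model: CVAE, noise_seed: int | None = None) -> float:
    """Negative ELBO of a batch (mean per image).

    With ``noise_seed=None`` the deterministic code z = mu is used.  Pixels
    must lie in [0, 1].
    """
    batch = np.asarray(batch, dtype=float)
    if batch.size == 0:
        raise ValueError("empty batch")
    if batch.min() < 0 or batch.max() > 1:
        raise ValueError("pixel values must lie in [0, 1]")
    eps = None
    if noise_seed is not None:
        b = batch.shape[0] if batch.ndim >= 3 else 1
        eps = np.random.default_rng(noise_seed).standard_normal((b, model.config.latent_dim))
    loss, _, _ = model.loss_and_grads(batch, eps, want_grads=False)
    return loss


def train(dataset: np.ndarray, config: CVAEConfig,
          on_epoch=None) -> tuple[CVAE, np.ndarray]:
    """Fit a CVAE on a stack of R-TFMs; returns (model, per-epoch mean loss)."""
    config.validate()
    data = np.asarray(dataset, dtype=float)
    if data.ndim != 3 or data.shape[1:] != (IMG, IMG):
        raise ValueError(f"expected (n, {IMG}, {IMG}) dataset")
    if data.shape[0] == 0:
        raise ValueError("empty dataset")
    if data.shape[0] < 2 * config.batch_size:
        raise ValueError("need at least 2 * batch_size images to train")
    if data.min() < 0 or data.max() > 1:
        raise ValueError("pixel values must lie in [0, 1]")
    model = build_model(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n = data.shape[0]
    history = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        total = 0.0
        for s in range(0, n, config.batch_size):
            idx = order[s:s + config.batch_size]
            batch = data[idx]
            eps = rng.standard_normal((len(idx), config.latent_dim))
            loss, _, _ = model.loss_and_grads(batch, eps)
            model._adam_step(config.learning_rate)
            total += loss * len(idx)
        history.append(total / n)
        if on_epoch is not None:
            model.trained = True
            on_epoch(_epoch + 1, model)
    model.trained = True
    return model, np.asarray(history)


def save_model(model: CVAE, path: str) -> None:
    """Persist parameters and configuration to a single .npz checkpoint."""
    arrays = {}
    for li, layer in enumerate(model._layers()):
        for name, p, _ in layer.params():
            arrays[f"layer{li}_{name}"] = p
    cfg = model.config
    arrays["_config"] = np.asarray([cfg.latent_dim, cfg.epochs, cfg.batch_size,
                                    cfg.learning_rate, cfg.seed], dtype=float)
    arrays["_likelihood"] = np.asarray(cfg.likelihood)
    arrays["_trained"] = np.asarray(int(model.trained))
    np.savez(path, **arrays)


def load_model(path: str) -> CVAE:
    with np.load(path, allow_pickle=False) as data:
        c = data["_config"]
        cfg = CVAEConfig(latent_dim=int(c[0]), epochs=int(c[1]), batch_size=int(c[2]),
                         learning_rate=float(c[3]), seed=int(c[4]),
                         likelihood=str(data["_likelihood"]))
        model = CVAE(cfg)
        for li, layer in enumerate(model._layers()):
            for name, p, _ in layer.params():
                p[...] = data[f"layer{li}_{name}"].astype(p.dtype)
        model.trained = bool(int(data["_trained"]))
    return model


def encode_latent(model: CVAE, image: np.ndarray,
                  noise_seed: int | None = 0) -> LatentCode:
    """Posterior parameters and sampled code for a single image."""
    mu, lv = model.encode(np.asarray(image)[None] if np.asarray(image).ndim == 2
                          else np.asarray(image))
    log_sigma = 0.5 * lv.astype(float)
    z = reparameterize(mu.astype(float), log_sigma, noise_seed)
    return LatentCode(mu=mu[0].astype(float), log_sigma=log_sigma[0], z=z[0])


def reconstruct(dataset: np.ndarray, model: CVAE, batch_size: int = 64) -> np.ndarray:
    """Deterministic reconstructions (z = mu) of a stack of images."""
    if not isinstance(model, CVAE):
        raise TypeError("expected a CVAE model")
    if not model.trained:
        raise ValueError("model has not been trained")
    return reconstruct_raw(dataset, model, batch_size)


def reconstruct_raw(dataset: np.ndarray, model: CVAE, batch_size: int = 64) -> np.ndarray:
    """Like :func:`reconstruct` but allowed on an untrained model (baselines)."""
    data = np.asarray(dataset, dtype=float)
    if data.ndim == 2:
        data = data[None]
    out = np.empty_like(data)
    for s in range(0, data.shape[0], batch_size):
        mu, _ = model.encode(data[s:s + batch_size])
        out[s:s + batch_size] = model.decode(mu)
    return out
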