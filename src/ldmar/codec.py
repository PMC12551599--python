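"""Vector-quantized autoencoder (codebook-clustered VQ-VAE) for CT slices.

Maps windowed attenuation slices to a compact quantized latent grid and
back.  Training minimizes the four-term composite objective

    L = MSE(f, f0) + ||sg[z_e] - z_q||^2 + beta * ||z_e - sg[z_q]||^2
        + lambda_p * perceptual(f, f0)

where ``sg`` is the stop-gradient operator: the codebook term moves code
vectors toward encoder outputs, the commitment term moves encoder outputs
toward their codes, and neither derivative crosses ``sg``.  Dead codes
(rarely used vectors) are periodically re-anchored to cluster centers of
recently seen encoder features so the codebook stays live.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Image2D
from .nn import Adam, Conv2d, Module, Param, ResBlock, Upsample2x
from .perceptual import PerceptualExtractor

__all__ = [
    "Codebook",
    "LatentCode",
    "CodecLossParts",
    "VQCodec",
    "codec_loss",
    "vq_grads",
    "refresh_dead_codes",
    "train_codec",
    "DEFAULT_WINDOW",
]

# attenuation window (mm^-1) mapped linearly to [-1, 1] before encoding
DEFAULT_WINDOW = (-0.02, 0.10)


def window_normalize(values: np.ndarray, window=DEFAULT_WINDOW) -> np.ndarray:
    lo, hi = window
    return np.clip(2.0 * (values - lo) / (hi - lo) - 1.0, -1.0, 1.0)


def window_denormalize(values: np.ndarray, window=DEFAULT_WINDOW) -> np.ndarray:
    lo, hi = window
    return (values + 1.0) / 2.0 * (hi - lo) + lo


@dataclass
class Codebook:
    """K x D table of code vectors with per-code usage counters."""

    vectors: np.ndarray
    usage: np.ndarray = None

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("codebook must be K x D")
        if self.usage is None:
            self.usage = np.zeros(self.vectors.shape[0])

    @property
    def k(self) -> int:
        return self.vectors.shape[0]

    @property
    def d(self) -> int:
        return self.vectors.shape[1]


@dataclass
class LatentCode:
    """Continuous encoder output, code assignments and the quantized grid.

    ``grid`` and ``quantized`` are (D, h, w); ``indices`` is (h, w).
    """

    grid: np.ndarray
    indices: np.ndarray
    quantized: np.ndarray

    def __post_init__(self):
        if self.grid.shape != self.quantized.shape:
            raise ValueError("grid and quantized shapes differ")
        if self.indices.shape != self.grid.shape[1:]:
            raise ValueError("indices shape inconsistent with grid")


@dataclass
class CodecLossParts:
    recon: float
    codebook_term: float
    commit_term: float
    perceptual: float
    beta: float
    lambda_p: float

    @property
    def total(self) -> float:
        return self.recon + self.codebook_term + self.commit_term + self.lambda_p * self.perceptual


def quantize(ze: np.ndarray, book: Codebook) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-code assignment of a (D, h, w) grid; returns (indices, zq)."""
    d, h, w = ze.shape
    flat = ze.reshape(d, -1).T  # (hw, D)
    d2 = ((flat[:, None, :] - book.vectors[None, :, :]) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)
    zq = book.vectors[idx].T.reshape(d, h, w)
    return idx.reshape(h, w), zq


class VQCodec(Module):
    """Encoder/decoder pair around a shared codebook; downsample factor 4."""

    def __init__(
        self,
        k: int = 128,
        d: int = 4,
        channels: tuple[int, int] = (16, 32),
        window=DEFAULT_WINDOW,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        c0, c1 = channels
        self.window = tuple(window)
        self.downsample_factor = 4
        # encoder
        self.e_in = Conv2d(1, c0, 3, 1, rng)
        self.e_b0 = ResBlock(c0, c0, rng=rng)
        self.e_d1 = Conv2d(c0, c1, 3, 2, rng)
        self.e_b1 = ResBlock(c1, c1, rng=rng)
        self.e_d2 = Conv2d(c1, c1, 3, 2, rng)
        self.e_b2 = ResBlock(c1, c1, rng=rng)
        self.e_out = Conv2d(c1, d, 3, 1, rng, init_gain=0.2)
        # decoder
        self.d_in = Conv2d(d, c1, 3, 1, rng)
        self.d_b2 = ResBlock(c1, c1, rng=rng)
        self.d_u2 = Upsample2x()
        self.d_c2 = Conv2d(c1, c1, 3, 1, rng)
        self.d_b1 = ResBlock(c1, c1, rng=rng)
        self.d_u1 = Upsample2x()
        self.d_c1 = Conv2d(c1, c0, 3, 1, rng)
        self.d_b0 = ResBlock(c0, c0, rng=rng)
        self.d_out = Conv2d(c0, 1, 3, 1, rng, init_gain=0.2)
        self.codebook = Codebook(rng.normal(0.0, 0.5, size=(k, d)))
        self.trained = False

    # --- raw network passes on (N, C, H, W) batches -----------------------
    def encode_batch(self, x: np.ndarray) -> np.ndarray:
        h = self.e_in.forward(x)
        h = self.e_b0.forward(h)
        h = self.e_d1.forward(h)
        h = self.e_b1.forward(h)
        h = self.e_d2.forward(h)
        h = self.e_b2.forward(h)
        return self.e_out.forward(h)

    def encode_backward(self, dze: np.ndarray) -> np.ndarray:
        dh = self.e_out.backward(dze)
        dh, _ = self.e_b2.backward(dh)
        dh = self.e_d2.backward(dh)
        dh, _ = self.e_b1.backward(dh)
        dh = self.e_d1.backward(dh)
        dh, _ = self.e_b0.backward(dh)
        return self.e_in.backward(dh)

    def decode_batch(self, z: np.ndarray) -> np.ndarray:
        h = self.d_in.forward(z)
        h = self.d_b2.forward(h)
        h = self.d_c2.forward(self.d_u2.forward(h))
        h = self.d_b1.forward(h)
        h = self.d_c1.forward(self.d_u1.forward(h))
        h = self.d_b0.forward(h)
        return self.d_out.forward(h)

    def decode_backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.d_out.backward(dout)
        dh, _ = self.d_b0.backward(dh)
        dh = self.d_u1.backward(self.d_c1.backward(dh))
        dh, _ = self.d_b1.backward(dh)
        dh = self.d_u2.backward(self.d_c2.backward(dh))
        dh, _ = self.d_b2.backward(dh)
        return self.d_in.backward(dh)

    # --- public image-level API -------------------------------------------
    def encode(self, image: Image2D | np.ndarray) -> LatentCode:
        values = image.values if isinstance(image, Image2D) else np.asarray(image)
        if values.shape[0] % self.downsample_factor:
            pad_to = -(-values.shape[0] // self.downsample_factor) * self.downsample_factor
            raise ValueError(
                f"image side {values.shape[0]} not divisible by "
                f"{self.downsample_factor}; pad to {pad_to}"
            )
        x = window_normalize(values, self.window)[None, None]
        ze = self.encode_batch(x)[0]
        idx, zq = quantize(ze, self.codebook)
        return LatentCode(grid=ze, indices=idx, quantized=zq)

    def decode(self, code: LatentCode | np.ndarray, pixel_size: float = 1.0) -> Image2D:
        z = code.quantized if isinstance(code, LatentCode) else np.asarray(code)
        y = self.decode_batch(z[None])[0, 0]
        return Image2D(window_denormalize(y, self.window), pixel_size)

    def roundtrip(self, image: Image2D) -> Image2D:
        return self.decode(self.encode(image), image.pixel_size)


def codec_loss(
    f: np.ndarray,
    f0: np.ndarray,
    ze: np.ndarray,
    zq: np.ndarray,
    beta: float = 0.25,
    lambda_p: float = 0.01,
    feat: PerceptualExtractor | None = None,
) -> CodecLossParts:
    """Composite loss parts; stop-gradient affects derivatives, not values.

    ``recon`` is the mean squared error between reconstruction and original;
    the codebook and commitment terms are squared L2 norms of z_e - z_q.
    """
    if beta < 0 or lambda_p < 0:
        raise ValueError("weights must be non-negative")
    recon = float(np.mean((f - f0) ** 2))
    v2 = float(np.sum((ze - zq) ** 2))
    perc = 0.0
    if feat is not None:
        a = f[None, None] if f.ndim == 2 else f
        b = f0[None, None] if f0.ndim == 2 else f0
        perc = feat.distance(a, b)
    return CodecLossParts(
        recon=recon, codebook_term=v2, commit_term=beta * v2, perceptual=perc,
        beta=beta, lambda_p=lambda_p,
    )


def vq_grads(ze: np.ndarray, zq: np.ndarray, beta: float = 0.25):
    """Stop-gradient-routed derivatives of the two VQ terms.

    Returns (d/d_encoder, d/d_codes): the codebook term ||sg[z_e] - z_q||^2
    contributes only to the code vectors, the commitment term
    beta * ||z_e - sg[z_q]||^2 only to the encoder output.
    """
    g_encoder = 2.0 * beta * (ze - zq)
    g_codes = 2.0 * (zq - ze)
    return g_encoder, g_codes


def refresh_dead_codes(
    book: Codebook,
    recent_features: np.ndarray,
    threshold: float = 1.0,
    rng_seed: int = 0,
) -> Codebook:
    """Re-anchor rarely used codes to cluster centers of unassigned features.

    ``recent_features`` is an (M, D) buffer of encoder outputs.  Codes with
    ``usage < threshold`` are moved to k-means centers computed over the
    features that are currently far from every live code, which spreads the
    codebook into occupied regions of feature space.  Deterministic for a
    fixed seed; returns a new Codebook (usage preserved, dead entries reset).
    """
    feats = np.asarray(recent_features, dtype=np.float64)
    if feats.ndim != 2 or feats.shape[0] == 0:
        raise ValueError("recent_features must be a non-empty (M, D) buffer")
    dead = np.nonzero(book.usage < threshold)[0]
    if dead.size == 0:
        return Codebook(book.vectors.copy(), book.usage.copy())
    d2 = ((feats[:, None, :] - book.vectors[None, :, :]) ** 2).sum(axis=2)
    far_order = np.argsort(-d2.min(axis=1))
    pool = feats[far_order[: max(8 * dead.size, 32)]]
    if pool.shape[0] >= dead.size > 1:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=dead.size, n_init=1, random_state=rng_seed)
        km.fit(pool)
        centers = km.cluster_centers_
    else:
        centers = pool[: dead.size]
        if centers.shape[0] < dead.size:
            centers = np.resize(centers, (dead.size, feats.shape[1]))
    vectors = book.vectors.copy()
    vectors[dead] = centers
    usage = book.usage.copy()
    usage[dead] = threshold  # fresh start for re-anchored codes
    return Codebook(vectors, usage)


def train_codec(
    images: list[np.ndarray],
    n_steps: int = 300,
    batch_size: int = 4,
    lr: float = 2e-4,
    beta: float = 0.25,
    lambda_p: float = 0.01,
    k: int = 128,
    d: int = 4,
    channels: tuple[int, int] = (16, 32),
    window=DEFAULT_WINDOW,
    seed: int = 0,
    usage_decay: float = 0.99,
    refresh_every: int = 50,
    refresh_threshold: float = 0.1,
    feat: PerceptualExtractor | None = None,
    warmup_frac: float = 0.4,
    callback=None,
) -> VQCodec:
    """Desk-scale codec training on raw attenuation slices.

    The first ``warmup_frac`` of the steps train encoder/decoder without the
    quantization bottleneck (continuous latents straight to the decoder);
    the codebook is then seeded from the warmed-up feature distribution and
    trained jointly.  The VQ gradient terms are mean-reduced inside the
    update (same minima, better-conditioned steps); reported loss parts
    follow the norm-squared definitions of :func:`codec_loss`.
    Straight-through estimation passes the decoder gradient to the encoder
    unchanged.
    """
    rng = np.random.default_rng(seed)
    codec = VQCodec(k=k, d=d, channels=channels, window=window, seed=seed + 1)
    if feat is None and lambda_p > 0:
        feat = PerceptualExtractor(seed=seed + 2)
    data = np.stack([window_normalize(np.asarray(im), window) for im in images])[:, None]
    book = codec.codebook
    book_param = Param(book.vectors)
    opt = Adam(list(codec.params()) + [book_param], lr=lr)
    book_init = False
    n_warm = int(warmup_frac * n_steps)
    feat_buffer = []
    for step in range(n_steps):
        idx = rng.integers(0, data.shape[0], size=batch_size)
        x = data[idx]
        ze = codec.encode_batch(x)  # (N, D, h, w)
        n, dd, h, w = ze.shape
        if step < n_warm:
            # continuous warm-up: no bottleneck, pure autoencoding
            f = codec.decode_batch(ze)
            codec.zero_grad()
            dout = 2.0 * (f - x) / f.size
            if feat is not None and lambda_p > 0:
                _, gp = feat.distance_and_grad(f, x)
                dout = dout + lambda_p * gp
            codec.encode_backward(codec.decode_backward(dout))
            opt.step()
            if callback is not None:
                callback(step, codec_loss(f[0, 0], x[0, 0], ze[0], ze[0], beta, lambda_p, None))
            continue
        flat = ze.transpose(0, 2, 3, 1).reshape(-1, dd)
        if not book_init:
            # seed the codebook from the first batch's feature distribution
            pick = rng.choice(flat.shape[0], size=book.k, replace=flat.shape[0] < book.k)
            book_param.value[...] = flat[pick] + 0.01 * rng.normal(size=(book.k, dd))
            book_init = True
        dist = ((flat[:, None, :] - book_param.value[None, :, :]) ** 2).sum(axis=2)
        assign = dist.argmin(axis=1)
        zq_flat = book_param.value[assign]
        zq = zq_flat.reshape(n, h, w, dd).transpose(0, 3, 1, 2)
        # usage statistics and dead-code refresh
        book.usage *= usage_decay
        np.add.at(book.usage, assign, 1.0)
        feat_buffer.append(flat[:: max(1, flat.shape[0] // 64)])
        if refresh_every and (step + 1) % refresh_every == 0:
            buf = np.concatenate(feat_buffer[-8:], axis=0)
            book.vectors = book_param.value
            refreshed = refresh_dead_codes(
                book, buf, threshold=refresh_threshold * batch_size, rng_seed=seed + step
            )
            book_param.value[...] = refreshed.vectors
            book.usage[...] = refreshed.usage

        f = codec.decode_batch(zq)
        codec.zero_grad()
        book_param.zero_grad()
        dout = 2.0 * (f - x) / f.size
        if feat is not None and lambda_p > 0:
            _, gp = feat.distance_and_grad(f, x)
            dout = dout + lambda_p * gp
        dz_dec = codec.decode_backward(dout)
        # straight-through + mean-reduced commitment
        g_enc_vq, g_codes = vq_grads(ze, zq, beta)
        codec.encode_backward(dz_dec + g_enc_vq / ze.size)
        # codebook moves by the (mean-reduced) codebook-loss gradient
        g_codes_flat = g_codes.transpose(0, 2, 3, 1).reshape(-1, dd) / ze.size
        np.add.at(book_param.grad, assign, g_codes_flat)
        opt.step()
        if callback is not None:
            parts = codec_loss(f[0, 0], x[0, 0], ze[0], zq[0], beta, lambda_p, None)
            callback(step, parts)
    book.vectors = book_param.value
    codec.trained = True
    return codec
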