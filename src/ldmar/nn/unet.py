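"""A compact U-Net with optional sinusoidal time conditioning.

Three resolution scales, residual conv blocks, nearest-neighbour upsampling
and skip concatenation.  The same class serves as the diffusion noise
estimator (with ``temb_dim`` set and the condition channels concatenated to
the input) and as the metal-segmentation network (no time embedding, one
output logit channel).
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2d, GroupNorm, Linear, Module, SiLU

__all__ = ["ResBlock", "UNet", "time_embedding"]


def time_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    """Sinusoidal (cosine/sine pair) embedding of integer timesteps; (N, dim)."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    ang = t[:, None] * freqs[None, :]
    return np.concatenate([np.cos(ang), np.sin(ang)], axis=1)


class ResBlock(Module):
    """Pre-activation residual block: x + conv(silu(norm(conv(silu(norm(x)))))).

    The second convolution is small-initialized so the block starts close to
    the identity, which keeps activation variance flat with depth and makes
    early optimization well-conditioned.  Time conditioning (when
    ``temb_dim`` is set) is added as a per-channel bias after the first
    convolution.
    """

    def __init__(self, cin: int, cout: int, temb_dim: int | None = None, rng=None, norm=True):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(cin, cout, 3, 1, rng)
        self.conv2 = Conv2d(cout, cout, 3, 1, rng, init_gain=0.05)
        self.n1 = GroupNorm(cin) if norm else None
        self.n2 = GroupNorm(cout) if norm else None
        self.a1 = SiLU()
        self.a2 = SiLU()
        self.proj = Linear(temb_dim, cout, rng) if temb_dim else None
        self.skip = Conv2d(cin, cout, 1, 1, rng) if cin != cout else None

    def forward(self, x: np.ndarray, temb: np.ndarray | None = None) -> np.ndarray:
        h = self.n1.forward(x) if self.n1 is not None else x
        h = self.a1.forward(h)
        h = self.conv1.forward(h)
        if self.proj is not None:
            h = h + self.proj.forward(temb)[:, :, None, None]
        h = self.n2.forward(h) if self.n2 is not None else h
        h = self.a2.forward(h)
        h = self.conv2.forward(h)
        s = self.skip.forward(x) if self.skip is not None else x
        return h + s

    def backward(self, dy: np.ndarray):
        """Returns (dx, dtemb); dtemb is None when unconditioned."""
        ds = dy
        dh = self.conv2.backward(dy)
        dh = self.a2.backward(dh)
        if self.n2 is not None:
            dh = self.n2.backward(dh)
        dtemb = None
        if self.proj is not None:
            dtemb = self.proj.backward(dh.sum(axis=(2, 3)))
        dh = self.conv1.backward(dh)
        dh = self.a1.backward(dh)
        if self.n1 is not None:
            dh = self.n1.backward(dh)
        dx = dh + (self.skip.backward(ds) if self.skip is not None else ds)
        return dx, dtemb


class UNet(Module):
    """Three-scale U-Net; input spatial side must be divisible by 4."""

    def __init__(
        self,
        cin: int,
        cout: int,
        channels: tuple[int, int, int] = (16, 32, 64),
        temb_dim: int | None = None,
        rng=None,
        norm: bool = True,
    ):
        rng = rng or np.random.default_rng(0)
        c0, c1, c2 = channels
        self.temb_dim = temb_dim
        if temb_dim:
            self.t1 = Linear(temb_dim, temb_dim, rng)
            self.t_act = SiLU()
            self.t2 = Linear(temb_dim, temb_dim, rng)
        self.enc0 = ResBlock(cin, c0, temb_dim, rng, norm)
        self.down1 = Conv2d(c0, c1, 3, 2, rng)
        self.enc1 = ResBlock(c1, c1, temb_dim, rng, norm)
        self.down2 = Conv2d(c1, c2, 3, 2, rng)
        self.mid = ResBlock(c2, c2, temb_dim, rng, norm)
        self.up2 = Conv2d(c2, c1, 3, 1, rng)
        self.dec1 = ResBlock(2 * c1, c1, temb_dim, rng, norm)
        self.up1 = Conv2d(c1, c0, 3, 1, rng)
        self.dec0 = ResBlock(2 * c0, c0, temb_dim, rng, norm)
        self.out = Conv2d(c0, cout, 3, 1, rng, init_gain=0.05)
        from .layers import Upsample2x

        self.us2 = Upsample2x()
        self.us1 = Upsample2x()
        self._c1 = c1
        self._c0 = c0

    def _temb(self, t: np.ndarray | None, n: int) -> np.ndarray | None:
        if not self.temb_dim:
            return None
        from .unet import time_embedding

        e = time_embedding(t, self.temb_dim)
        if e.shape[0] == 1 and n > 1:
            e = np.repeat(e, n, axis=0)
        self._temb_sin = e
        h = self.t1.forward(e)
        h = self.t_act.forward(h)
        return self.t2.forward(h)

    def forward(self, x: np.ndarray, t: np.ndarray | float | None = None) -> np.ndarray:
        temb = self._temb(t, x.shape[0])
        h0 = self.enc0.forward(x, temb)
        h1 = self.enc1.forward(self.down1.forward(h0), temb)
        hm = self.mid.forward(self.down2.forward(h1), temb)
        u2 = self.up2.forward(self.us2.forward(hm))
        d1 = self.dec1.forward(np.concatenate([u2, h1], axis=1), temb)
        u1 = self.up1.forward(self.us1.forward(d1))
        d0 = self.dec0.forward(np.concatenate([u1, h0], axis=1), temb)
        return self.out.forward(d0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dtembs = []

        def note(dt):
            if dt is not None:
                dtembs.append(dt)

        dd0 = self.out.backward(dy)
        dcat0, dt = self.dec0.backward(dd0)
        note(dt)
        du1, dh0_skip = dcat0[:, : self._c0], dcat0[:, self._c0 :]
        dd1 = self.us1.backward(self.up1.backward(du1))
        dcat1, dt = self.dec1.backward(dd1)
        note(dt)
        du2, dh1_skip = dcat1[:, : self._c1], dcat1[:, self._c1 :]
        dhm = self.us2.backward(self.up2.backward(du2))
        dh_mid, dt = self.mid.backward(dhm)
        note(dt)
        dh1 = self.down2.backward(dh_mid) + dh1_skip
        dh1, dt = self.enc1.backward(dh1)
        note(dt)
        dh0 = self.down1.backward(dh1) + dh0_skip
        dx, dt = self.enc0.backward(dh0)
        note(dt)
        if self.temb_dim and dtembs:
            dtemb = np.sum(dtembs, axis=0)
            dh = self.t2.backward(dtemb)
            dh = self.t_act.backward(dh)
            self.t1.backward(dh)
        return dx
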