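"""Layer-wise perceptual feature distance with a fixed convolutional stack.

The perceptual term compares images through the feature maps of a
multi-layer convolutional network with unit channel weights.  The default
extractor uses fixed, seeded random filters: it preserves the structure of
the loss (zero iff features match, layer-weighted squared distances) without
requiring any downloaded weights, and random multi-scale projections are a
serviceable carrier of structural differences.  Any object exposing the same
``features`` / ``distance_and_grad`` interface (e.g. a pretrained stack) can
be substituted.
"""

from __future__ import annotations

import numpy as np

from .nn import Conv2d, SiLU

__all__ = ["PerceptualExtractor"]


class PerceptualExtractor:
    """Fixed 3-scale random conv stack; not trainable."""

    def __init__(self, cin: int = 1, channels=(8, 16, 32), seed: int = 1234):
        rng = np.random.default_rng(seed)
        self.convs = []
        self.acts = []
        c_prev = cin
        for c in channels:
            self.convs.append(Conv2d(c_prev, c, 3, 2, rng))
            self.acts.append(SiLU())
            c_prev = c
        self.layer_weights = np.ones(len(channels))

    def features(self, x: np.ndarray) -> list[np.ndarray]:
        """Feature maps at every scale for a (N, C, H, W) batch."""
        feats = []
        h = x
        for conv, act in zip(self.convs, self.acts):
            h = act.forward(conv.forward(h))
            feats.append(h)
        return feats

    def distance(self, a: np.ndarray, b: np.ndarray) -> float:
        """Sum over layers of w_l * mean squared feature difference."""
        fa = self.features(a)
        fb = self.features(b)
        return float(
            sum(w * np.mean((x - y) ** 2) for w, x, y in zip(self.layer_weights, fa, fb))
        )

    def distance_and_grad(self, a: np.ndarray, b: np.ndarray):
        """Perceptual distance and its gradient w.r.t. ``a`` (b held fixed)."""
        fb = self.features(b)
        # forward on a, keeping caches layer by layer
        hs = [a]
        h = a
        for conv, act in zip(self.convs, self.acts):
            h = act.forward(conv.forward(h))
            hs.append(h)
        value = float(
            sum(w * np.mean((x - y) ** 2) for w, x, y in zip(self.layer_weights, hs[1:], fb))
        )
        # reverse pass: caches in convs/acts are from the 'a' forward
        grad = None
        for li in reversed(range(len(self.convs))):
            dlayer = 2.0 * self.layer_weights[li] * (hs[li + 1] - fb[li]) / hs[li + 1].size
            d = dlayer if grad is None else grad + dlayer
            d = self.acts[li].backward(d)
            grad = self.convs[li].backward(d)
        return value, grad
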