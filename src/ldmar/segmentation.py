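"""Metal segmentation: dataset synthesis, compound loss, training, inference.

Thresholding an artifact-bearing reconstruction is brittle: bright streaks
get masked, saturated teeth get confused with implants.  The network
alternative is trained on synthesized samples built by rotating
phantom-derived artifact maps (corrupted minus clean, which carry both the
metal and its artifact pattern) onto metal-free slices, with the rotated
metal masks as labels.  Training uses the compound Dice + binary
cross-entropy loss on sigmoid outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .codec import DEFAULT_WINDOW, window_normalize
from .geometry import Image2D
from .nn import Adam, UNet, sigmoid
from .phantom import PhantomPair, extract_artifact_map, overlay_artifact

__all__ = [
    "SegSample",
    "SegLossParts",
    "synthesize_seg_dataset",
    "pseudo_label",
    "seg_loss",
    "SegModel",
    "train_seg",
    "segment_metal",
]


@dataclass
class SegSample:
    """Artifact-bearing input slice with its binary metal label."""

    input: Image2D
    label: np.ndarray
    source: str = "phantom_derived"  # or pseudo_label

    def __post_init__(self):
        self.label = np.asarray(self.label).astype(bool)
        if self.label.shape != self.input.values.shape:
            raise ValueError("label must share the input grid")


@dataclass
class SegLossParts:
    dice: float
    bce: float

    @property
    def total(self) -> float:
        return self.dice + self.bce


def synthesize_seg_dataset(
    pairs: list[PhantomPair],
    clean_slices: list[Image2D],
    n_out: int,
    rng_seed: int = 0,
) -> list[SegSample]:
    """Build ``n_out`` training samples by artifact-map transfer.

    Each sample overlays a randomly rotated artifact map from one of the
    phantom pairs onto one of the metal-free slices; the identically rotated
    metal mask is the label.  Deterministic for a fixed seed.
    """
    if not pairs or not clean_slices:
        raise ValueError("need at least one phantom pair and one clean slice")
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(n_out):
        pair = pairs[rng.integers(0, len(pairs))]
        target = clean_slices[rng.integers(0, len(clean_slices))]
        amap = extract_artifact_map(pair.corrupted, pair.clean)
        angle = float(rng.uniform(0.0, 360.0))
        composite, mask = overlay_artifact(amap, target, pair.metal_mask, rotation_deg=angle)
        out.append(SegSample(composite, mask, "phantom_derived"))
    return out


def pseudo_label(
    image: Image2D,
    block_size: int = 15,
    offset: float = 0.05,
    bright_fraction: float = 0.6,
    closing_radius: int = 1,
    min_area: int = 4,
) -> np.ndarray:
    """Approximate metal mask by adaptive thresholding plus morphology.

    A pixel is a candidate when it exceeds its ``block_size`` local mean by
    ``offset`` (attenuation units) AND exceeds ``bright_fraction`` of the
    image's 99.9th percentile — metal saturates reconstructions far above
    bone, so both criteria hold for implants and fail for teeth and
    streaks.  Candidates are closed, hole-filled and cleaned of tiny blobs.
    An empty mask is a legal outcome.
    """
    v = image.values
    if not np.all(np.isfinite(v)):
        raise ValueError("image contains non-finite values")
    local_mean = ndimage.uniform_filter(v, size=block_size)
    cand = v > (local_mean + offset)
    cand &= v > bright_fraction * np.percentile(v, 99.9)
    if closing_radius > 0:
        cand = ndimage.binary_closing(cand, structure=morphology.disk(closing_radius))
    cand = ndimage.binary_fill_holes(cand)
    return _drop_small(cand, min_area)


def _drop_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove connected components smaller than ``min_area`` pixels."""
    if min_area <= 0 or not mask.any():
        return mask
    lbl, n = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, range(1, n + 1))
    keep = np.nonzero(sizes >= min_area)[0] + 1
    return np.isin(lbl, keep)


def seg_loss(pred: np.ndarray, label: np.ndarray, eps: float = 1e-7) -> SegLossParts:
    """Compound loss: soft Dice + mean binary cross-entropy."""
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(label, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError("prediction and label shapes differ")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("predictions must lie in [0, 1]")
    inter = float((p * g).sum())
    dice = 1.0 - 2.0 * inter / (p.sum() + g.sum() + eps)
    pc = np.clip(p, eps, 1.0 - eps)
    bce = float(-np.mean(g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)))
    return SegLossParts(dice=dice, bce=bce)


@dataclass
class SegModel:
    """Trained U-Net with its input normalization window."""

    net: UNet
    window: tuple[float, float] = DEFAULT_WINDOW
    trained: bool = False

    def logits(self, values: np.ndarray) -> np.ndarray:
        x = window_normalize(values, self.window)[None, None]
        return self.net.forward(x)[0, 0]


def _dice_bce_grad(p: np.ndarray, g: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    """d(dice + bce)/d(logits) for sigmoid outputs p."""
    s = p.sum() + g.sum() + eps
    inter = (p * g).sum()
    d_dice_dp = -2.0 * g / s + 2.0 * inter / s**2
    # bce through sigmoid collapses to (p - g) / N
    d_bce_dlogit = (p - g) / p.size
    d_dice_dlogit = d_dice_dp * p * (1.0 - p)
    return d_dice_dlogit + d_bce_dlogit


def train_seg(
    samples: list[SegSample],
    n_steps: int = 400,
    batch_size: int = 8,
    lr: float = 2e-3,
    channels: tuple[int, int, int] = (8, 16, 32),
    window=DEFAULT_WINDOW,
    seed: int = 0,
    callback=None,
) -> SegModel:
    """Train the compact segmentation U-Net on synthesized samples."""
    if not samples:
        raise ValueError("no training samples")
    rng = np.random.default_rng(seed)
    x = np.stack([window_normalize(s.input.values, window) for s in samples])[:, None]
    g = np.stack([s.label.astype(np.float64) for s in samples])[:, None]
    net = UNet(1, 1, channels, rng=np.random.default_rng(seed + 1))
    opt = Adam(net.params(), lr=lr)
    for step in range(n_steps):
        idx = rng.integers(0, x.shape[0], size=batch_size)
        logits = net.forward(x[idx])
        p = sigmoid(logits)
        net.zero_grad()
        grad = np.stack([_dice_bce_grad(p[i, 0], g[idx][i, 0]) for i in range(len(idx))])[
            :, None
        ] / len(idx)
        net.backward(grad)
        opt.step()
        if callback is not None and step % 50 == 0:
            parts = seg_loss(p[0, 0], g[idx][0, 0])
            callback(step, parts)
    return SegModel(net=net, window=tuple(window), trained=True)


def segment_metal(image: Image2D, model: SegModel, min_area: int = 4) -> np.ndarray:
    """Binary metal mask from a trained model (0.5 threshold, tiny blobs removed)."""
    if not model.trained:
        raise RuntimeError("segmentation model is untrained")
    prob = sigmoid(model.logits(image.values))
    return _drop_small(prob > 0.5, min_area)


def dice_score(a: np.ndarray, b: np.ndarray, eps: float = 1e-7) -> float:
    """Hard Dice overlap of two binary masks."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    return float(2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum() + eps))
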