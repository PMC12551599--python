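"""Classical projection-domain metal artifact reduction.

The chain implemented here is the analytic backbone the learned prior plugs
into: compute the metal trace (projection-domain footprint of the metal
mask), fill it either directly (LIMAR: linear interpolation along the
detector axis) or in a prior-normalized sinogram (NMAR: divide by the
forward projection of a prior image, inpaint the trace in the flattened
domain, multiply back).  Entries outside the trace are never touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .geometry import FanBeamGeometry, Image2D, Sinogram
from .projector import forward_project

__all__ = [
    "TraceMask",
    "PriorImage",
    "compute_metal_trace",
    "limar",
    "build_threshold_prior",
    "nmar_correct",
    "reinsert_metal",
    "inpaint_trace",
]


@dataclass
class TraceMask:
    """Binary [n_views x n_detectors] footprint of the metal in projection space."""

    values: np.ndarray
    provenance: str = "projected_mask"
    dilation_margin: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("trace mask must be 2-D")


@dataclass
class PriorImage:
    """An artifact-free image estimate guiding NMAR, with its provenance."""

    image: Image2D
    provenance: str = "threshold_prior"  # or ldm_prior / oracle_clean


def compute_metal_trace(
    metal_mask: np.ndarray | Image2D,
    geometry: FanBeamGeometry,
    pixel_size: float | None = None,
    margin: int = 1,
) -> TraceMask:
    """Exact projection-domain footprint of a binary metal mask.

    A detector bin is flagged at a view iff the source->element ray line
    intersects at least one metal pixel square; the footprint is then dilated
    by ``margin`` bins along the detector axis to absorb projector edge
    effects.  The geometric test is exact (corner straddling + slab overlap),
    so it matches a brute-force ray/pixel intersection check.
    """
    if isinstance(metal_mask, Image2D):
        pixel_size = metal_mask.pixel_size
        mask = metal_mask.values.astype(bool)
    else:
        mask = np.asarray(metal_mask).astype(bool)
        if pixel_size is None:
            raise ValueError("pixel_size required for a bare mask array")
    n = mask.shape[0]
    trace = np.zeros((geometry.n_views, geometry.n_detectors), dtype=bool)
    if not mask.any():
        return TraceMask(trace, "projected_mask", margin)

    c = (n - 1) / 2.0
    rows, cols = np.nonzero(mask)
    # pixel square corners in world coordinates
    px = (cols - c) * pixel_size
    py = (rows - c) * pixel_size
    h = pixel_size / 2.0
    corners = np.stack(
        [
            np.stack([px - h, py - h], -1),
            np.stack([px - h, py + h], -1),
            np.stack([px + h, py - h], -1),
            np.stack([px + h, py + h], -1),
        ],
        axis=1,
    )  # (P, 4, 2)

    r_si = geometry.source_to_isocenter
    u = geometry.detector_coords()
    for v, beta in enumerate(geometry.angles):
        src = r_si * np.array([np.cos(beta), np.sin(beta)])
        e_beta = np.array([np.cos(beta), np.sin(beta)])
        e_u = np.array([-np.sin(beta), np.cos(beta)])
        det = src[None, :] - geometry.source_to_detector * e_beta[None, :] + u[:, None] * e_u[None, :]
        d = det - src[None, :]  # (D, 2)
        # signed distance of each pixel corner to each ray line
        rel = corners - src[None, None, :]  # (P, 4, 2)
        cross = d[:, None, None, 0] * rel[None, :, :, 1] - d[:, None, None, 1] * rel[None, :, :, 0]
        straddles = (cross.min(axis=2) <= 0) & (cross.max(axis=2) >= 0)  # (D, P)
        trace[v] = straddles.any(axis=1)

    if margin > 0:
        structure = np.zeros((1, 2 * margin + 1), dtype=bool)
        structure[0, :] = True
        trace = ndimage.binary_dilation(trace, structure=structure)
    return TraceMask(trace, "projected_mask", margin)


def limar(sino: Sinogram, trace: TraceMask) -> Sinogram:
    """Linear-interpolation MAR along the detector axis.

    Traced runs are replaced by linear interpolation between the nearest
    untraced neighbours in the same view; runs touching a row edge take the
    single available neighbour's value (constant extension).  A fully traced
    view falls back to the nearest view with untraced data (with a warning).
    """
    t = trace.values
    if t.shape != sino.values.shape:
        raise ValueError("trace shape does not match sinogram")
    out = sino.values.copy()
    n_det = out.shape[1]
    cols = np.arange(n_det)
    full_rows = []
    for v in range(out.shape[0]):
        tr = t[v]
        if not tr.any():
            continue
        if tr.all():
            full_rows.append(v)
            continue
        out[v, tr] = np.interp(cols[tr], cols[~tr], out[v, ~tr])
    for v in full_rows:
        ok = np.nonzero(~t.all(axis=1))[0]
        if ok.size == 0:
            raise ValueError("every view is fully traced; nothing to interpolate from")
        nearest = ok[np.argmin(np.abs(ok - v))]
        warnings.warn(
            f"view {v} fully traced; copying values from view {nearest}", stacklevel=2
        )
        out[v] = out[nearest]
    return sino.like(out)


def build_threshold_prior(
    image: Image2D,
    t_soft: float = 0.010,
    t_bone: float = 0.032,
    soft_value: float = 0.022,
    smooth_sigma: float = 0.0,
) -> PriorImage:
    """Piecewise-flat prior: air -> 0, soft tissue -> ``soft_value``, bone kept.

    This is the classical NMAR prior construction from an uncorrected image;
    thresholds are in mm^-1 on the reconstruction.
    """
    if not t_soft < t_bone:
        raise ValueError("require t_soft < t_bone")
    v = image.values
    prior = np.where(v < t_soft, 0.0, np.where(v < t_bone, soft_value, v))
    if smooth_sigma > 0:
        prior = ndimage.gaussian_filter(prior, smooth_sigma)
    return PriorImage(image.like(prior), "threshold_prior")


def inpaint_trace(normalized: np.ndarray, trace: np.ndarray, mode: str = "harmonic") -> np.ndarray:
    """Fill traced entries of a (views x detectors) grid.

    ``mode='linear'``: per-view linear interpolation along the detector axis.
    ``mode='harmonic'``: solve Laplace's equation on the traced region over
    the 2-D view x detector grid with Dirichlet boundary from untraced
    neighbours, which couples adjacent views and avoids view-to-view jitter.
    """
    if mode == "linear":
        out = normalized.copy()
        cols = np.arange(normalized.shape[1])
        for v in range(normalized.shape[0]):
            tr = trace[v]
            if tr.any() and not tr.all():
                out[v, tr] = np.interp(cols[tr], cols[~tr], out[v, ~tr])
            elif tr.all():
                out[v, tr] = np.nan  # resolved below from neighbouring views
        if np.isnan(out).any():
            bad = np.nonzero(np.isnan(out).any(axis=1))[0]
            good = np.nonzero(~np.isnan(out).any(axis=1))[0]
            for v in bad:
                out[v] = out[good[np.argmin(np.abs(good - v))]]
        return out
    if mode != "harmonic":
        raise ValueError(f"unknown inpaint mode {mode!r}")

    out = normalized.copy()
    idx = -np.ones(trace.shape, dtype=np.int64)
    ys, xs = np.nonzero(trace)
    if ys.size == 0:
        return out
    idx[ys, xs] = np.arange(ys.size)
    rows_l, cols_l, data, rhs = [], [], [], np.zeros(ys.size)
    nv, nd = trace.shape
    for k, (i, j) in enumerate(zip(ys, xs)):
        deg = 0
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ii, jj = i + di, j + dj
            if not (0 <= ii < nv and 0 <= jj < nd):
                continue
            deg += 1
            if trace[ii, jj]:
                rows_l.append(k)
                cols_l.append(idx[ii, jj])
                data.append(-1.0)
            else:
                rhs[k] += normalized[ii, jj]
        rows_l.append(k)
        cols_l.append(k)
        data.append(float(deg))
    lap = sparse.csr_matrix((data, (rows_l, cols_l)), shape=(ys.size, ys.size))
    out[ys, xs] = spsolve(lap, rhs)
    return out


def nmar_correct(
    sino: Sinogram,
    prior: PriorImage,
    trace: TraceMask,
    geometry: FanBeamGeometry | None = None,
    eps: float | None = None,
    inpaint_mode: str = "harmonic",
) -> Sinogram:
    """Normalized MAR with an arbitrary prior image.

    q = max(FP(prior), eps); the measured sinogram is divided by q, the trace
    is inpainted in this flattened domain, and the result is multiplied back
    by q.  Entries outside the trace are returned bit-identical to the input.
    ``eps`` defaults to 1e-4 times the median positive prior projection.
    """
    geometry = geometry or sino.geometry
    if trace.values.shape != sino.values.shape:
        raise ValueError("trace shape does not match sinogram")
    if np.any(prior.image.values < 0):
        prior = PriorImage(prior.image.like(np.maximum(prior.image.values, 0.0)), prior.provenance)
    q = forward_project(prior.image, geometry).values
    if eps is None:
        pos = q[q > 0]
        eps = 1e-4 * float(np.median(pos)) if pos.size else 1e-8
    if eps <= 0:
        raise ValueError("eps must be positive")
    q = np.maximum(q, eps)
    normalized = sino.values / q
    filled = inpaint_trace(normalized, trace.values, mode=inpaint_mode)
    out = sino.values.copy()
    out[trace.values] = (filled * q)[trace.values]
    return sino.like(out)


def reinsert_metal(corrected: Image2D, metal_mask: np.ndarray, original: Image2D) -> Image2D:
    """Copy the original image's values back onto the metal pixels."""
    if corrected.values.shape != original.values.shape or corrected.values.shape != metal_mask.shape:
        raise ValueError("corrected, original and mask must share the grid")
    out = corrected.values.copy()
    m = metal_mask.astype(bool)
    out[m] = original.values[m]
    return corrected.like(out)
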