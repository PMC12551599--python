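"""Fan-beam forward projection, its exact adjoint, and filtered backprojection.

The forward projector samples each source->detector ray at half-pixel steps
and gathers image values by bilinear interpolation (Joseph-style line
integration); the backprojector scatters with the same weights, so
``backproject`` is the exact adjoint of ``forward_project`` up to float
round-off.  ``fbp_reconstruct`` implements the standard equispaced-detector
fan-beam FBP: cosine pre-weighting on the virtual detector through the
isocenter, ramp filtering, and distance-weighted backprojection, with Parker
weights applied automatically for short scans (arc < 360 degrees).
"""

from __future__ import annotations

import numpy as np

from .geometry import FanBeamGeometry, Image2D, Sinogram

__all__ = [
    "forward_project",
    "backproject",
    "fbp_reconstruct",
    "SUPPORTED_FILTERS",
]

SUPPORTED_FILTERS = ("ramp", "cosine", "hann")


def _ray_samples(geometry: FanBeamGeometry, image: Image2D):
    """Per-view sampling positions shared by projector and adjoint.

    Returns (sources, unit ray directions [n_views, n_det, 2], t grid, dt).
    """
    r_si = geometry.source_to_isocenter
    angles = geometry.angles
    src = r_si * np.stack([np.cos(angles), np.sin(angles)], axis=-1)  # (V, 2)

    u = geometry.detector_coords()  # (D,)
    # detector element centers in world coordinates, per view
    e_beta = np.stack([np.cos(angles), np.sin(angles)], axis=-1)  # (V, 2)
    e_u = np.stack([-np.sin(angles), np.cos(angles)], axis=-1)  # (V, 2)
    det = (
        src[:, None, :]
        - geometry.source_to_detector * e_beta[:, None, :]
        + u[None, :, None] * e_u[:, None, :]
    )  # (V, D, 2)
    d = det - src[:, None, :]
    d /= np.linalg.norm(d, axis=-1, keepdims=True)

    half_diag = image.extent * np.sqrt(2.0) / 2.0
    dt = image.pixel_size / 2.0
    t0, t1 = r_si - half_diag, r_si + half_diag
    n_s = int(np.ceil((t1 - t0) / dt))
    t = t0 + (np.arange(n_s) + 0.5) * dt  # midpoint rule
    return src, d, t, dt


def _grid_coords(points: np.ndarray, image: Image2D):
    """World (x, y) -> fractional array coordinates (row, col)."""
    c = (image.n - 1) / 2.0
    col = points[..., 0] / image.pixel_size + c
    row = points[..., 1] / image.pixel_size + c
    return row, col


def _bilinear_gather(values: np.ndarray, row: np.ndarray, col: np.ndarray) -> np.ndarray:
    """Bilinear interpolation with zero outside the grid."""
    n = values.shape[0]
    r0 = np.floor(row).astype(np.int64)
    c0 = np.floor(col).astype(np.int64)
    fr = row - r0
    fc = col - c0
    out = np.zeros(row.shape, dtype=np.float64)
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr = r0 + dr
        cc = c0 + dc
        ok = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
        out[ok] += w[ok] * values[rr[ok], cc[ok]]
    return out


def _bilinear_scatter(acc: np.ndarray, row: np.ndarray, col: np.ndarray, w_in: np.ndarray) -> None:
    """Adjoint of ``_bilinear_gather``: accumulate weights into ``acc`` in place."""
    n = acc.shape[0]
    r0 = np.floor(row).astype(np.int64)
    c0 = np.floor(col).astype(np.int64)
    fr = row - r0
    fc = col - c0
    flat = acc.ravel()
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr = r0 + dr
        cc = c0 + dc
        ok = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
        idx = rr[ok] * n + cc[ok]
        flat += np.bincount(idx, weights=(w_in * w)[ok], minlength=flat.size)


def _check_fov(image: Image2D, geometry: FanBeamGeometry) -> None:
    support = image.extent / 2.0  # inscribed-circle radius of the grid
    fov = geometry.fov_radius
    if fov > 0 and support > fov * 1.0001:
        raise ValueError(
            f"image support radius {support:.1f} mm exceeds the scan field of view "
            f"({fov:.1f} mm); enlarge the detector or shrink the image"
        )


def forward_project(image: Image2D, geometry: FanBeamGeometry) -> Sinogram:
    """Line integrals of ``image`` along every source->detector-element ray."""
    _check_fov(image, geometry)
    src, d, t, dt = _ray_samples(geometry, image)
    out = np.empty((geometry.n_views, geometry.n_detectors), dtype=np.float64)
    for v in range(geometry.n_views):
        pts = src[v, None, None, :] + d[v, :, None, :] * t[None, :, None]  # (D, S, 2)
        row, col = _grid_coords(pts, image)
        out[v] = _bilinear_gather(image.values, row, col).sum(axis=1) * dt
    return Sinogram(out, geometry)


def backproject(sinogram: Sinogram, image_template: Image2D) -> Image2D:
    """Unfiltered backprojection; exact adjoint of :func:`forward_project`."""
    geometry = sinogram.geometry
    _check_fov(image_template, geometry)
    src, d, t, dt = _ray_samples(geometry, image_template)
    acc = np.zeros((image_template.n, image_template.n), dtype=np.float64)
    for v in range(geometry.n_views):
        pts = src[v, None, None, :] + d[v, :, None, :] * t[None, :, None]
        row, col = _grid_coords(pts, image_template)
        w = np.broadcast_to(sinogram.values[v][:, None] * dt, row.shape)
        _bilinear_scatter(acc, row, col, np.ascontiguousarray(w, dtype=np.float64))
    return Image2D(acc, image_template.pixel_size)


def _ramp_kernel(n: int, tau: float) -> np.ndarray:
    """Discrete ramp (Ram-Lak) convolution kernel, sample spacing ``tau``."""
    k = np.arange(-n, n + 1)
    h = np.zeros(k.shape, dtype=np.float64)
    h[k == 0] = 1.0 / (4.0 * tau**2)
    odd = k % 2 != 0
    h[odd] = -1.0 / (np.pi * k[odd] * tau) ** 2
    return h


def _filter_rows(p: np.ndarray, tau: float, filter_name: str) -> np.ndarray:
    """Ramp-filter every row of ``p`` (convolution via zero-padded FFT)."""
    if filter_name not in SUPPORTED_FILTERS:
        raise ValueError(
            f"unsupported filter {filter_name!r}; supported: {', '.join(SUPPORTED_FILTERS)}"
        )
    n_det = p.shape[1]
    size = 1
    while size < 2 * n_det + 1:
        size *= 2
    h = _ramp_kernel(n_det, tau)
    hf = np.fft.rfft(np.roll(np.pad(h, (0, size - h.size)), -n_det))
    if filter_name != "ramp":
        f = np.fft.rfftfreq(size, d=tau)
        f_nyq = 1.0 / (2.0 * tau)
        if filter_name == "cosine":
            hf = hf * np.cos(np.pi * f / (2.0 * f_nyq))
        elif filter_name == "hann":
            hf = hf * 0.5 * (1.0 + np.cos(np.pi * f / f_nyq))
    pf = np.fft.rfft(p, n=size, axis=1)
    q = np.fft.irfft(pf * hf[None, :], n=size, axis=1)[:, :n_det]
    return q * tau


def _parker_weights(geometry: FanBeamGeometry) -> np.ndarray:
    """Parker short-scan weights over [0, pi + 2*gamma_max]; (V, D) array."""
    s = geometry.virtual_detector_coords()
    gamma = np.arctan2(s, geometry.source_to_isocenter)  # fan angle per element
    gmax = np.abs(gamma).max()
    beta = geometry.angles - geometry.angles[0]
    b, g = np.meshgrid(beta, gamma, indexing="ij")
    w = np.ones_like(b)
    with np.errstate(invalid="ignore", divide="ignore"):
        w_in = np.sin(np.pi / 4 * b / (gmax - g)) ** 2
        w_out = np.sin(np.pi / 4 * (np.pi + 2 * gmax - b) / (gmax + g)) ** 2
    ramp_in = b < 2 * (gmax - g)
    w[ramp_in] = w_in[ramp_in]
    ramp_out = b > np.pi - 2 * g
    w[ramp_out] = w_out[ramp_out]
    w[b > np.pi + 2 * gmax] = 0.0  # redundant tail beyond the short-scan range
    return np.clip(np.nan_to_num(w, nan=1.0), 0.0, 1.0)


def fbp_reconstruct(
    sinogram: Sinogram,
    image_template: Image2D | int,
    filter_name: str = "ramp",
    pixel_size: float | None = None,
) -> Image2D:
    """Filtered backprojection onto the template grid.

    ``image_template`` may be an :class:`Image2D` (its values are ignored) or
    an integer grid size, in which case ``pixel_size`` must be given.
    """
    if isinstance(image_template, int):
        if pixel_size is None:
            raise ValueError("pixel_size required when image_template is a size")
        image_template = Image2D(np.zeros((image_template, image_template)), pixel_size)
    geometry = sinogram.geometry
    r_si = geometry.source_to_isocenter

    s = geometry.virtual_detector_coords()
    tau = geometry.detector_pitch / geometry.magnification

    # cosine pre-weighting on the virtual detector
    p = sinogram.values * (r_si / np.sqrt(r_si**2 + s**2))[None, :]

    arc = np.deg2rad(geometry.arc_degrees)
    if arc < 2 * np.pi - 1e-6:
        p = p * _parker_weights(geometry)
        scale = 1.0
    else:
        scale = 0.5  # every ray measured twice over a full turn

    q = _filter_rows(p, tau, filter_name)

    n = image_template.n
    ax, ay = image_template.pixel_centers()
    x = ax[None, :] * np.ones((n, 1))  # column j -> x
    y = ay[:, None] * np.ones((1, n))  # row i -> y

    d_beta = arc / geometry.n_views
    recon = np.zeros((n, n), dtype=np.float64)
    for v, beta in enumerate(geometry.angles):
        cb, sb = np.cos(beta), np.sin(beta)
        # distance from the source plane: r_si - projection onto e_beta
        denom = r_si - (x * cb + y * sb)
        u_virt = r_si * (-x * sb + y * cb) / denom
        w = (r_si / denom) ** 2
        recon += w * np.interp(u_virt, s, q[v], left=0.0, right=0.0)
    recon *= d_beta * scale
    return Image2D(recon, image_template.pixel_size)
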