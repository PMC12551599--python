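"""Synthetic dental phantoms and polychromatic projection simulation.

The simulator emulates the data a half-arch dental scan produces: a soft
tissue body (PMMA-like), a horseshoe arch of bone-equivalent (Teflon-like)
teeth sockets, an air throat, and titanium inserts seated inside some of the
sockets.  Projections are polychromatic (Beer-Lambert per energy bin under a
bremsstrahlung-like spectrum) with Poisson photon noise, which produces the
two canonical metal artifacts: dark bands between inserts (beam hardening)
and noisy streaks (photon statistics/starvation).  A paired "clean" slice is
obtained by replacing metal with bone-equivalent material and simulating a
monoenergetic, noise-free scan, mirroring how a physical two-scan phantom
pair is acquired.

Artifact maps (corrupted minus clean) can be rotated and overlaid onto
arbitrary metal-free slices to build training sets for the metal
segmentation network.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .geometry import FanBeamGeometry, Image2D, Sinogram
from .projector import fbp_reconstruct, forward_project

__all__ = [
    "MATERIALS",
    "AIR",
    "SOFT",
    "BONE",
    "METAL",
    "MaterialMap",
    "Spectrum",
    "PhantomSpec",
    "PhantomPair",
    "make_dental_phantom",
    "attenuation_image",
    "simulate_polychromatic",
    "make_phantom_pair",
    "generate_pairs",
    "extract_artifact_map",
    "overlay_artifact",
    "default_spectrum",
    "default_geometry",
    "effective_mono_energy",
    "mu_of",
]

AIR, SOFT, BONE, METAL = 0, 1, 2, 3
_LABEL_NAMES = {AIR: "air", SOFT: "soft_tissue", BONE: "bone", METAL: "metal"}


def _material_coeffs(anchors: dict[str, tuple[tuple[float, float], tuple[float, float]]]):
    """Solve the two-component attenuation model from two (keV, mm^-1) anchors.

    mu(E) = a * (E/30)^-3  +  b * kn(E), with kn a slowly decreasing
    Compton-like factor.  Both basis functions are non-negative and
    non-increasing over the diagnostic range, so mu(E) is too whenever
    a, b >= 0 (asserted at definition time).
    """
    out = {}
    for name, ((e1, m1), (e2, m2)) in anchors.items():
        A = np.array(
            [
                [(e1 / 30.0) ** -3, _kn(e1)],
                [(e2 / 30.0) ** -3, _kn(e2)],
            ]
        )
        a, b = np.linalg.solve(A, np.array([m1, m2]))
        if a < 0 or b < 0:
            raise ValueError(f"non-physical coefficients for {name}: {a}, {b}")
        out[name] = (float(a), float(b))
    return out


def _kn(e_kev):
    """Compton-like energy factor, normalized to 1 at 30 keV."""
    x = np.asarray(e_kev, dtype=np.float64) / 511.0
    x0 = 30.0 / 511.0
    return (1.0 + x0) / (1.0 + x) * (1.0 + x0 * x0) / (1.0 + x * x)


# approximate anchor points (keV, mm^-1): water-equivalent soft tissue,
# Teflon-like bone surrogate, titanium; ordering and energy dependence are
# what matters here, not dosimetric accuracy
MATERIALS = _material_coeffs(
    {
        "air": ((40.0, 0.0), (80.0, 0.0)),
        "soft_tissue": ((40.0, 0.027), (80.0, 0.018)),
        "bone": ((40.0, 0.056), (80.0, 0.036)),
        "metal": ((40.0, 0.27), (80.0, 0.10)),
    }
)
_LABEL_MATERIAL = {AIR: "air", SOFT: "soft_tissue", BONE: "bone", METAL: "metal"}


def mu_of(label: int, energies: np.ndarray) -> np.ndarray:
    """Attenuation (mm^-1) of a material label at the given energies (keV)."""
    a, b = MATERIALS[_LABEL_MATERIAL[label]]
    e = np.asarray(energies, dtype=np.float64)
    return a * (e / 30.0) ** -3 + b * _kn(e)


@dataclass(frozen=True)
class Spectrum:
    """Discrete X-ray spectrum: energy bins (keV) and normalized weights."""

    energies: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=np.float64)
        w = np.asarray(self.weights, dtype=np.float64)
        if e.ndim != 1 or e.shape != w.shape:
            raise ValueError("energies and weights must be matching 1-D arrays")
        if not np.all(np.diff(e) > 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w / w.sum())

    @property
    def effective_energy(self) -> float:
        return float(np.sum(self.energies * self.weights))

    @classmethod
    def monoenergetic(cls, e_kev: float) -> "Spectrum":
        return cls(np.array([e_kev]), np.array([1.0]))


def default_spectrum(kvp: float = 95.0, n_bins: int = 12, filtration: float = 0.5) -> Spectrum:
    """Filtered bremsstrahlung-like tube spectrum up to ``kvp`` keV.

    Kramers-law shape (E_max - E) attenuated by an aluminium-like inherent
    filtration that suppresses the soft end of the spectrum.
    """
    e = np.linspace(20.0, kvp - 2.0, n_bins)
    w = np.maximum(kvp - e, 0.0)
    mu_filter = 0.08 * (e / 30.0) ** -3 + 0.02  # per-mm aluminium-like
    w = w * np.exp(-mu_filter * filtration)
    return Spectrum(e, w)


def effective_mono_energy(
    spectrum: Spectrum, path_mm: float = 60.0
) -> float:
    """Monoenergetic energy equivalent to the spectrum for a soft-tissue path.

    Solves mu_soft(E) * L = -ln( sum_E w exp(-mu_soft(E) L) ) for E at a
    representative body path length L.  Using this energy for the clean
    reference scan centres the polychromatic offset of soft tissue near zero,
    so the difference map isolates metal artifacts rather than a global bias.
    """
    from scipy.optimize import brentq

    mu_s = mu_of(SOFT, spectrum.energies)
    p_poly = -np.log(np.sum(spectrum.weights * np.exp(-mu_s * path_mm)))
    mu_target = p_poly / path_mm
    a, b = MATERIALS["soft_tissue"]

    def f(e):
        return a * (e / 30.0) ** -3 + b * _kn(e) - mu_target

    return float(brentq(f, spectrum.energies[0], spectrum.energies[-1] + 60.0))


def default_geometry(n_views: int = 180, n_det: int = 128, pitch_mm: float = 1.6) -> FanBeamGeometry:
    """Desk-scale full-fan geometry comfortably covering a 64 x 1.25 mm slice."""
    return FanBeamGeometry.make(
        sid_mm=500.0, sdd_mm=1000.0, n_det=n_det, pitch_mm=pitch_mm, n_views=n_views
    )


@dataclass
class MaterialMap:
    """Label grid plus pixel size; attenuation tables come from :data:`MATERIALS`."""

    labels: np.ndarray
    pixel_size: float
    soft_texture: np.ndarray | None = None  # multiplicative field on soft tissue

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.shape[0] != lab.shape[1]:
            raise ValueError("labels must be a square 2-D grid")
        if not np.isin(lab, list(_LABEL_NAMES)).all():
            raise ValueError("unknown material label present")
        self.labels = lab.astype(np.int8)

    def metal_mask(self) -> np.ndarray:
        return self.labels == METAL

    def without_metal(self) -> "MaterialMap":
        """Metal labels replaced by bone-equivalent (the paired clean phantom)."""
        lab = self.labels.copy()
        lab[lab == METAL] = BONE
        return MaterialMap(lab, self.pixel_size, self.soft_texture)


def attenuation_image(mat: MaterialMap, e_kev: float) -> Image2D:
    """Monoenergetic attenuation map of a material grid at ``e_kev``."""
    mu = np.zeros(mat.labels.shape, dtype=np.float64)
    for label in (SOFT, BONE, METAL):
        mu[mat.labels == label] = mu_of(label, e_kev)
    if mat.soft_texture is not None:
        soft = mat.labels == SOFT
        mu[soft] *= mat.soft_texture[soft]
    return Image2D(mu, mat.pixel_size)


@dataclass
class PhantomSpec:
    """Parameters of the dental-arch phantom generator.

    Distances in mm.  Randomized quantities (arch rotation, which sockets
    carry metal, soft-tissue texture) are drawn from the seed passed to
    :func:`make_dental_phantom`.
    """

    image_size: int = 64
    pixel_size: float = 1.25
    body_radius: float = 36.0
    arch_radius: float = 24.0
    arch_span_deg: float = 200.0
    n_teeth: int = 9
    tooth_radius: float = 3.8
    throat_radius: float = 9.0
    throat_offset: float = 10.0  # posterior shift of the air throat
    n_metal: int = 2
    metal_radius: float = 3.0
    metal_shape: str = "cylinder"  # or "screw"
    randomize_rotation: bool = True
    texture_amplitude: float = 0.04
    texture_sigma_px: float = 4.0

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _disc(X, Y, cx, cy, r):
    return (X - cx) ** 2 + (Y - cy) ** 2 <= r**2


def make_dental_phantom(spec: PhantomSpec, rng_seed: int) -> MaterialMap:
    """Generate a labeled dental phantom; deterministic for a fixed seed.

    Metal inserts sit inside bone sockets along the arch.  Raises if an
    insert would extend past the phantom body.
    """
    rng = np.random.default_rng(rng_seed)
    n = spec.image_size
    c = (n - 1) / 2.0
    ax = (np.arange(n) - c) * spec.pixel_size
    X = ax[None, :] * np.ones((n, 1))
    Y = ax[:, None] * np.ones((1, n))

    labels = np.full((n, n), AIR, dtype=np.int8)
    labels[_disc(X, Y, 0, 0, spec.body_radius)] = SOFT

    rot = rng.uniform(0, 2 * np.pi) if spec.randomize_rotation else 0.0

    # teeth sockets along a horseshoe arc (opening towards the throat side)
    span = np.deg2rad(spec.arch_span_deg)
    th = np.linspace(-span / 2, span / 2, spec.n_teeth) + np.pi / 2 + rot
    tooth_xy = np.stack([spec.arch_radius * np.cos(th), spec.arch_radius * np.sin(th)], axis=1)
    for cx, cy in tooth_xy:
        if np.hypot(cx, cy) + spec.tooth_radius > spec.body_radius:
            raise ValueError("tooth socket extends past the phantom body")
        labels[_disc(X, Y, cx, cy, spec.tooth_radius)] = BONE

    # air throat posterior to the arch
    tx, ty = -spec.throat_offset * np.cos(rot + np.pi / 2), -spec.throat_offset * np.sin(
        rot + np.pi / 2
    )
    labels[_disc(X, Y, tx, ty, spec.throat_radius) & (labels == SOFT)] = AIR

    # metal inserts seated in a random subset of sockets
    if spec.n_metal > spec.n_teeth:
        raise ValueError("more metal inserts than sockets")
    if spec.metal_radius > spec.tooth_radius:
        raise ValueError("metal insert larger than its socket")
    chosen = rng.choice(spec.n_teeth, size=spec.n_metal, replace=False)
    for idx in np.sort(chosen):
        cx, cy = tooth_xy[idx]
        m = _disc(X, Y, cx, cy, spec.metal_radius)
        if spec.metal_shape == "screw":
            # cylinder head plus a narrower shaft pointing inward
            ux, uy = -cx / np.hypot(cx, cy), -cy / np.hypot(cx, cy)
            along = (X - cx) * ux + (Y - cy) * uy
            across = -(X - cx) * uy + (Y - cy) * ux
            shaft = (along >= 0) & (along <= 2.5 * spec.metal_radius) & (
                np.abs(across) <= 0.5 * spec.metal_radius
            )
            m = m | (shaft & _disc(X, Y, 0, 0, spec.body_radius - 1.0))
        elif spec.metal_shape != "cylinder":
            raise ValueError(f"unknown metal shape {spec.metal_shape!r}")
        labels[m] = METAL

    texture = None
    if spec.texture_amplitude > 0:
        noise = rng.normal(size=(n, n))
        low = ndimage.gaussian_filter(noise, spec.texture_sigma_px)
        low /= max(np.abs(low).max(), 1e-12)
        texture = 1.0 + spec.texture_amplitude * low
    return MaterialMap(labels, spec.pixel_size, texture)


def simulate_polychromatic(
    mat: MaterialMap,
    spectrum: Spectrum,
    geometry: FanBeamGeometry,
    photons_per_ray: float | None = 500.0,
    rng_seed: int | None = None,
) -> Sinogram:
    """Polychromatic line integrals with optional Poisson photon noise.

    detected = sum_E w(E) exp(-int mu(E));  sinogram = -ln(counts / blank),
    with counts floored at one photon (photon starvation).  A monoenergetic
    spectrum with noise disabled reduces exactly to the linear forward
    projection of the corresponding attenuation map.
    """
    if photons_per_ray is not None and photons_per_ray <= 0:
        raise ValueError("photons_per_ray must be positive (or None for noise-free)")
    detected = None
    for e, w in zip(spectrum.energies, spectrum.weights):
        p = forward_project(attenuation_image(mat, e), geometry).values
        term = w * np.exp(-p)
        detected = term if detected is None else detected + term
    if photons_per_ray is None or not np.isfinite(photons_per_ray):
        sino = -np.log(detected)
    else:
        rng = np.random.default_rng(rng_seed)
        counts = rng.poisson(photons_per_ray * detected).astype(np.float64)
        counts = np.maximum(counts, 1.0)  # photon starvation floor
        sino = -np.log(counts / photons_per_ray)
    return Sinogram(sino, geometry)


@dataclass
class PhantomPair:
    """Paired clean / metal-corrupted slice with its projection data."""

    clean: Image2D
    corrupted: Image2D
    corrupted_sino: Sinogram
    metal_mask: np.ndarray
    spec: PhantomSpec
    seed: int

    def __post_init__(self):
        if self.clean.values.shape != self.corrupted.values.shape:
            raise ValueError("clean and corrupted must share the grid")
        if self.metal_mask.shape != self.clean.values.shape:
            raise ValueError("metal mask must share the grid")
        self.metal_mask = self.metal_mask.astype(bool)


def make_phantom_pair(
    spec: PhantomSpec,
    geometry: FanBeamGeometry,
    spectrum: Spectrum,
    rng_seed: int,
    photons_per_ray: float | None = 500.0,
    filter_name: str = "ramp",
) -> PhantomPair:
    """Simulate one corrupted/clean pair.

    The corrupted slice is the FBP of a polychromatic, noisy scan of the
    phantom with metal.  The clean reference replaces metal with
    bone-equivalent and is reconstructed from a monoenergetic (spectrum
    effective energy), noise-free scan.
    """
    mat = make_dental_phantom(spec, rng_seed)
    sino_bad = simulate_polychromatic(
        mat, spectrum, geometry, photons_per_ray, rng_seed=rng_seed + 1
    )
    template = Image2D(np.zeros((spec.image_size, spec.image_size)), spec.pixel_size)
    corrupted = fbp_reconstruct(sino_bad, template, filter_name=filter_name)

    e_eff = effective_mono_energy(spectrum)
    clean_mat = mat.without_metal()
    sino_clean = simulate_polychromatic(
        clean_mat, Spectrum.monoenergetic(e_eff), geometry, photons_per_ray=None
    )
    clean = fbp_reconstruct(sino_clean, template, filter_name=filter_name)
    return PhantomPair(
        clean=clean,
        corrupted=corrupted,
        corrupted_sino=sino_bad,
        metal_mask=mat.metal_mask(),
        spec=spec,
        seed=rng_seed,
    )


def generate_pairs(
    n_pairs: int,
    spec: PhantomSpec | None = None,
    geometry: FanBeamGeometry | None = None,
    spectrum: Spectrum | None = None,
    seed: int = 0,
    photons_per_ray: float | None = 500.0,
) -> list[PhantomPair]:
    """Reproducible suite of phantom pairs; pair k uses seed ``seed + 1000*k``."""
    spec = spec or PhantomSpec()
    geometry = geometry or default_geometry()
    spectrum = spectrum or default_spectrum()
    return [
        make_phantom_pair(spec, geometry, spectrum, seed + 1000 * k, photons_per_ray)
        for k in range(n_pairs)
    ]


def extract_artifact_map(corrupted: Image2D, clean: Image2D) -> Image2D:
    """Difference map corrupted - clean (metal plus its artifacts)."""
    if corrupted.values.shape != clean.values.shape:
        raise ValueError("corrupted and clean must share the grid")
    return Image2D(corrupted.values - clean.values, corrupted.pixel_size)


def overlay_artifact(
    artifact: Image2D,
    target: Image2D,
    metal_mask: np.ndarray,
    rotation_deg: float | None = None,
    rng_seed: int | None = None,
) -> tuple[Image2D, np.ndarray]:
    """Rotate an artifact map and add it onto a metal-free target slice.

    Returns the composite image and the identically rotated metal mask.
    ``rotation_deg=None`` draws the angle uniformly from the seed.
    """
    if artifact.values.shape != target.values.shape:
        raise ValueError("artifact map and target must share the grid")
    if rotation_deg is None:
        rotation_deg = float(np.random.default_rng(rng_seed).uniform(0.0, 360.0))
    rot_map = ndimage.rotate(
        artifact.values, rotation_deg, reshape=False, order=1, mode="constant", cval=0.0
    )
    rot_mask = (
        ndimage.rotate(
            metal_mask.astype(np.float64),
            rotation_deg,
            reshape=False,
            order=1,
            mode="constant",
            cval=0.0,
        )
        > 0.5
    )
    return Image2D(target.values + rot_map, target.pixel_size), rot_mask
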