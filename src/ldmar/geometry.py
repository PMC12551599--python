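"""Acquisition geometry and the two working containers: images and sinograms.

Conventions used throughout the package:

* world coordinates (x, y) in mm, isocenter at the origin;
* image arrays are square, row index i maps to y, column index j to x, with
  the grid center at the isocenter and half-pixel sample positions:
  ``x_j = (j - (N-1)/2) * pixel_size``, ``y_i = (i - (N-1)/2) * pixel_size``;
* view angles in radians, counter-clockwise; the source sits at
  ``R_si * (cos b, sin b)`` and the flat detector is perpendicular to the
  source-isocenter line at distance ``R_sd`` from the source, with the
  detector coordinate u increasing along ``(-sin b, cos b)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FanBeamGeometry", "Image2D", "Sinogram"]


@dataclass(frozen=True)
class FanBeamGeometry:
    """Circular fan-beam scan with a flat, equally spaced detector."""

    source_to_isocenter: float
    source_to_detector: float
    n_detectors: int
    detector_pitch: float
    angles: np.ndarray
    arc_degrees: float
    detector_offset: float = 0.0

    def __post_init__(self) -> None:
        if not (self.source_to_detector > self.source_to_isocenter > 0):
            raise ValueError(
                "require source_to_detector > source_to_isocenter > 0, got "
                f"{self.source_to_detector} / {self.source_to_isocenter}"
            )
        if self.detector_pitch <= 0:
            raise ValueError("detector_pitch must be positive")
        if self.n_detectors < 2:
            raise ValueError("need at least 2 detector elements")
        angles = np.asarray(self.angles, dtype=np.float64)
        if angles.ndim != 1 or angles.size < 1:
            raise ValueError("angles must be a 1-D array")
        if angles.size > 1 and not np.all(np.diff(angles) > 0):
            raise ValueError("angles must be strictly increasing")
        object.__setattr__(self, "angles", angles)

    @classmethod
    def make(
        cls,
        sid_mm: float,
        sdd_mm: float,
        n_det: int,
        pitch_mm: float,
        n_views: int,
        arc_deg: float = 360.0,
        offset_mm: float = 0.0,
        start_deg: float = 0.0,
    ) -> "FanBeamGeometry":
        """Build a geometry with ``n_views`` equally spaced angles over ``arc_deg``."""
        angles = np.deg2rad(start_deg) + np.linspace(
            0.0, np.deg2rad(arc_deg), n_views, endpoint=False
        )
        return cls(
            source_to_isocenter=sid_mm,
            source_to_detector=sdd_mm,
            n_detectors=n_det,
            detector_pitch=pitch_mm,
            angles=angles,
            arc_degrees=arc_deg,
            detector_offset=offset_mm,
        )

    @classmethod
    def from_config(cls, cfg: dict) -> "FanBeamGeometry":
        """Build from the ``geometry.*`` block of a YAML config."""
        return cls.make(
            sid_mm=float(cfg["sid_mm"]),
            sdd_mm=float(cfg["sdd_mm"]),
            n_det=int(cfg["n_det"]),
            pitch_mm=float(cfg["pitch_mm"]),
            n_views=int(cfg["n_views"]),
            arc_deg=float(cfg.get("arc_deg", 360.0)),
            offset_mm=float(cfg.get("offset_mm", 0.0)),
        )

    @property
    def n_views(self) -> int:
        return int(self.angles.size)

    @property
    def magnification(self) -> float:
        return self.source_to_detector / self.source_to_isocenter

    def detector_coords(self) -> np.ndarray:
        """Physical u coordinate (mm) of each detector element center."""
        k = np.arange(self.n_detectors, dtype=np.float64)
        return (k - (self.n_detectors - 1) / 2.0) * self.detector_pitch + self.detector_offset

    def virtual_detector_coords(self) -> np.ndarray:
        """Detector coordinates rescaled onto the virtual detector through the isocenter."""
        return self.detector_coords() / self.magnification

    @property
    def fov_radius(self) -> float:
        """Radius (mm) of the isocentered disc covered by every view."""
        s = self.virtual_detector_coords()
        if s.min() >= 0 or s.max() <= 0:
            return 0.0  # detector entirely on one side (half-fan): no common disc
        return float(min(s.max(), -s.min()))

    def to_attrs(self) -> dict:
        return {
            "sid_mm": self.source_to_isocenter,
            "sdd_mm": self.source_to_detector,
            "n_det": self.n_detectors,
            "pitch_mm": self.detector_pitch,
            "offset_mm": self.detector_offset,
            "arc_deg": self.arc_degrees,
            "angles": self.angles,
        }

    @classmethod
    def from_attrs(cls, attrs: dict) -> "FanBeamGeometry":
        return cls(
            source_to_isocenter=float(attrs["sid_mm"]),
            source_to_detector=float(attrs["sdd_mm"]),
            n_detectors=int(attrs["n_det"]),
            detector_pitch=float(attrs["pitch_mm"]),
            detector_offset=float(attrs["offset_mm"]),
            arc_degrees=float(attrs["arc_deg"]),
            angles=np.asarray(attrs["angles"], dtype=np.float64),
        )


@dataclass
class Image2D:
    """Square attenuation map (mm^-1) with its pixel size in mm."""

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"image must be square 2-D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("image contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def extent(self) -> float:
        """Physical side length in mm."""
        return self.n * self.pixel_size

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x of columns, y of rows) in mm."""
        c = (self.n - 1) / 2.0
        ax = (np.arange(self.n) - c) * self.pixel_size
        return ax, ax

    def copy(self) -> "Image2D":
        return Image2D(self.values.copy(), self.pixel_size)

    def like(self, values: np.ndarray) -> "Image2D":
        return Image2D(np.asarray(values, dtype=np.float64), self.pixel_size)


@dataclass
class Sinogram:
    """Line integrals [n_views x n_detectors] tied to a fan-beam geometry."""

    values: np.ndarray
    geometry: FanBeamGeometry

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        expected = (self.geometry.n_views, self.geometry.n_detectors)
        if v.shape != expected:
            raise ValueError(f"sinogram shape {v.shape} != geometry shape {expected}")
        if not np.all(np.isfinite(v)):
            raise ValueError("sinogram contains non-finite values")
        self.values = v

    def copy(self) -> "Sinogram":
        return Sinogram(self.values.copy(), self.geometry)

    def like(self, values: np.ndarray) -> "Sinogram":
        return Sinogram(np.asarray(values, dtype=np.float64), self.geometry)
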