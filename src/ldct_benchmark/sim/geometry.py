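"""Parallel-beam acquisition geometry and sinogram container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GeometryError(ValueError):
    """Invalid acquisition geometry."""


@dataclass(frozen=True)
class Geometry:
    """2-D parallel-beam geometry applied slice-by-slice.

    Parameters
    ----------
    n_detectors
        Number of detector elements per view.
    detector_spacing
        Detector element pitch in mm.
    angles
        Projection angles in radians, strictly increasing, within [0, pi).
    image_size
        Reconstruction grid side length in voxels (square in-plane).
    fov
        Side length of the reconstructed field of view in mm.
    """

    n_detectors: int
    detector_spacing: float
    angles: np.ndarray
    image_size: int
    fov: float

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "angles", angles)
        if angles.ndim != 1 or angles.size < 1:
            raise GeometryError("angles must be a non-empty 1-D array")
        if np.any(np.diff(angles) <= 0):
            raise GeometryError("angles must be strictly increasing")
        if angles[0] < 0 or angles[-1] >= np.pi:
            raise GeometryError("angles must lie in [0, pi)")
        if self.n_detectors < 2 or self.image_size < 2:
            raise GeometryError("n_detectors and image_size must be >= 2")
        if self.detector_spacing <= 0 or self.fov <= 0:
            raise GeometryError("detector_spacing and fov must be positive")
        # the detector row must cover the image diagonal so no ray exits the FOV
        diagonal = np.sqrt(2.0) * self.fov
        if self.n_detectors * self.detector_spacing < diagonal - 1e-9:
            raise GeometryError(
                f"detector row ({self.n_detectors * self.detector_spacing:.1f} mm) "
                f"shorter than image diagonal ({diagonal:.1f} mm)"
            )

    @property
    def pixel_spacing(self) -> float:
        """In-plane voxel pitch in mm."""
        return self.fov / self.image_size

    @property
    def n_angles(self) -> int:
        return int(self.angles.size)

    @classmethod
    def standard(cls, image_size: int = 256, fov: float = 350.0, n_angles: int = 512) -> "Geometry":
        """Geometry with detector pitch equal to the pixel pitch and full diagonal coverage."""
        pitch = fov / image_size
        n_det = int(np.ceil(np.sqrt(2.0) * image_size)) + 3
        angles = np.arange(n_angles) * np.pi / n_angles
        return cls(n_detectors=n_det, detector_spacing=pitch, angles=angles, image_size=image_size, fov=fov)


@dataclass
class Sinogram:
    """Line-integral data, shape [n_angles, n_detectors] (dimensionless)."""

    data: np.ndarray
    geometry: Geometry
    dose_fraction: float = 1.0
    photons_per_ray: float = float("inf")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.geometry.n_angles, self.geometry.n_detectors):
            raise GeometryError(
                f"sinogram shape {self.data.shape} does not match geometry "
                f"({self.geometry.n_angles}, {self.geometry.n_detectors})"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram contains non-finite values")
        if not (0.0 < self.dose_fraction <= 1.0):
            raise ValueError("dose_fraction must lie in (0, 1]")
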