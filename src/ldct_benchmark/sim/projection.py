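"""Discrete Radon transform, projection-domain noise insertion, and FBP.

The forward projector is pixel-driven: each voxel's attenuation (weighted by
its area over the detector pitch) is splatted with linear interpolation onto
the detector coordinate t = x cos(theta) + y sin(theta). Backprojection is
the exact matrix transpose of this operation (gather with the same weights),
so <R x, y> = <x, R^T y> holds to machine precision — a property the noise
and reconstruction tests rely on.

Filtered back projection uses the standard band-limited discretization of
the ramp filter (spatial kernel h[0] = 1/(4 dt^2), h[n odd] = -1/(pi n dt)^2),
optionally Hann-apodized, applied by FFT with zero padding.
"""

from __future__ import annotations

import numpy as np

from ldct_benchmark.sim.geometry import Geometry, GeometryError, Sinogram

__all__ = ["forward_project", "backproject", "fbp", "insert_noise", "to_hu", "FILTERS"]

FILTERS = ("ramp", "hann")


def _pixel_grid(geometry: Geometry) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates (x, y) in mm, image center at the origin."""
    n = geometry.image_size
    h = geometry.pixel_spacing
    c = (n - 1) / 2.0
    idx = np.arange(n, dtype=float)
    x = (idx - c) * h                       # column -> x (mm, rightwards)
    y = (c - idx) * h                       # row -> y (mm, upwards)
    return np.meshgrid(x, y)                # shape (n, n) each


def _detector_coords(geometry: Geometry, theta: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear-interpolation indices and weight for every pixel at one view."""
    xx, yy = _pixel_grid(geometry)
    t = xx * np.cos(theta) + yy * np.sin(theta)
    u = t / geometry.detector_spacing + (geometry.n_detectors - 1) / 2.0
    i0 = np.floor(u).astype(np.int64)
    w1 = u - i0
    return i0.ravel(), w1.ravel(), u.ravel()


def forward_project(image: np.ndarray, geometry: Geometry) -> Sinogram:
    """Discrete parallel-beam Radon transform of a 2-D attenuation image.

    Parameters
    ----------
    image
        Square 2-D array of linear attenuation coefficients (1/mm) on the
        geometry's grid.
    geometry
        Acquisition geometry; the detector row must cover the image diagonal.

    Returns
    -------
    Sinogram
        Line integrals (dimensionless), shape [n_angles, n_detectors].
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise GeometryError("image must be square and 2-D")
    if image.shape[0] != geometry.image_size:
        raise GeometryError(f"image size {image.shape[0]} does not match geometry {geometry.image_size}")
    h = geometry.pixel_spacing
    weight = h * h / geometry.detector_spacing   # voxel area spread over detector pitch
    vals = image.ravel() * weight
    n_det = geometry.n_detectors
    sino = np.empty((geometry.n_angles, n_det), dtype=float)
    for a, theta in enumerate(geometry.angles):
        i0, w1, u = _detector_coords(geometry, float(theta))
        if u.min() < 0.0 or u.max() > n_det - 1:
            raise GeometryError("image support exceeds detector coverage (fov too large)")
        row = np.bincount(i0, weights=vals * (1.0 - w1), minlength=n_det + 1)
        row += np.bincount(i0 + 1, weights=vals * w1, minlength=n_det + 1)
        sino[a] = row[:n_det]
    return Sinogram(data=sino, geometry=geometry)


def backproject(sinogram: Sinogram) -> np.ndarray:
    """Unfiltered backprojection — the exact adjoint of :func:`forward_project`."""
    geom = sinogram.geometry
    h = geom.pixel_spacing
    weight = h * h / geom.detector_spacing
    n = geom.image_size
    image = np.zeros(n * n, dtype=float)
    data = sinogram.data
    for a, theta in enumerate(geom.angles):
        i0, w1, _ = _detector_coords(geom, float(theta))
        row = data[a]
        image += weight * ((1.0 - w1) * row[i0] + w1 * row[np.minimum(i0 + 1, geom.n_detectors - 1)])
    return image.reshape(n, n)


def _ramp_kernel(n_detectors: int, detector_spacing: float, filter_name: str) -> np.ndarray:
    """Frequency response of the discrete ramp filter on a zero-padded grid."""
    size = int(2 ** np.ceil(np.log2(2 * n_detectors)))
    # spatial-domain band-limited ramp
    n = np.concatenate([np.arange(0, size // 2 + 1), np.arange(size // 2 - 1, 0, -1)])
    kernel = np.zeros(size)
    kernel[0] = 1.0 / (4.0 * detector_spacing**2)
    odd = n % 2 == 1
    kernel[odd] = -1.0 / (np.pi * n[odd] * detector_spacing) ** 2
    response = np.real(np.fft.fft(kernel))
    if filter_name == "hann":
        freq = np.fft.fftfreq(size)
        response = response * 0.5 * (1.0 + np.cos(2.0 * np.pi * freq))
    elif filter_name != "ramp":
        raise ValueError(f"unknown filter {filter_name!r}; choose from {FILTERS}")
    return response


def fbp(sinogram: Sinogram, filter_name: str = "ramp") -> np.ndarray:
    """Filtered back projection to a linear-attenuation image (1/mm).

    Linear in the sinogram. ``filter_name`` is ``"ramp"`` (Ram-Lak) or
    ``"hann"`` (Hann-apodized ramp).
    """
    geom = sinogram.geometry
    if geom.n_angles < 2:
        raise GeometryError("FBP requires at least 2 projection angles")
    response = _ramp_kernel(geom.n_detectors, geom.detector_spacing, filter_name)
    size = response.size
    padded = np.zeros((geom.n_angles, size))
    padded[:, : geom.n_detectors] = sinogram.data
    filtered = np.real(np.fft.ifft(np.fft.fft(padded, axis=1) * response[None, :], axis=1))
    filtered = filtered[:, : geom.n_detectors] * geom.detector_spacing
    image = backproject(Sinogram(data=filtered, geometry=geom))
    # backproject carries h^2/dt per view; standard FBP wants pi/n_angles per view
    h = geom.pixel_spacing
    scale = (np.pi / geom.n_angles) * geom.detector_spacing / (h * h)
    return image * scale


def insert_noise(
    sinogram: Sinogram,
    dose_fraction: float,
    photons_per_ray: float,
    seed: int | np.random.Generator,
) -> Sinogram:
    """Simulate a reduced-dose acquisition by Poisson noise in the projection domain.

    Per ray, the transmitted photon count is drawn as
    ``N ~ Poisson(d * I0 * exp(-p))`` and the noisy line integral recovered as
    ``p' = -ln(max(N, 1) / (d * I0))``. The count clamp at one photon keeps
    p' finite in photon-starved rays.

    Parameters
    ----------
    dose_fraction
        d in (0, 1]; fraction of the full tube current-time product.
    photons_per_ray
        I0, unattenuated photon count per ray at full dose.
    seed
        Integer seed or an existing generator.
    """
    if not (0.0 < dose_fraction <= 1.0):
        raise ValueError("dose_fraction must lie in (0, 1]")
    if photons_per_ray <= 0:
        raise ValueError("photons_per_ray must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(int(seed))
    i0 = dose_fraction * photons_per_ray
    expected = i0 * np.exp(-sinogram.data)
    counts = rng.poisson(expected).astype(float)
    counts = np.maximum(counts, 1.0)
    noisy = -np.log(counts / i0)
    return Sinogram(
        data=noisy,
        geometry=sinogram.geometry,
        dose_fraction=dose_fraction,
        photons_per_ray=photons_per_ray,
    )


def to_hu(attenuation_image: np.ndarray, mu_water: float) -> np.ndarray:
    """Convert linear attenuation (1/mm) to Hounsfield units: 1000 (mu - mu_w)/mu_w."""
    if mu_water <= 0:
        raise ValueError("mu_water must be positive")
    return 1000.0 * (np.asarray(attenuation_image, dtype=float) - mu_water) / mu_water
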