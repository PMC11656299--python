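"""Full-reference image-quality metrics and physical CT metrics.

SSIM follows Wang et al.'s original recipe (11x11 truncated Gaussian window,
sigma 1.5, K1 = 0.01, K2 = 0.03, no sample-covariance correction, border of
half a window cropped). VIF is the pixel-domain multi-scale variant: a
Gaussian scale-space with four levels, local statistics from Gaussian
windows, and the ratio of distorted-to-reference information terms
accumulated over scales. PSNR and RMSE are computed on Hounsfield values
against a fixed, configurable data range so that scores are comparable
across scans and methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "DEFAULT_DATA_RANGE",
    "IdenticalImagesError",
    "MetricRecord",
    "CircularROI",
    "LineSegment",
    "ssim",
    "psnr",
    "rmse_hu",
    "vif",
    "cnr",
    "ct_number_deviation",
    "line_profile",
    "lesion_metrics",
]

#: default full-scale HU range used for SSIM/PSNR/VIF normalization
DEFAULT_DATA_RANGE = 2000.0


class IdenticalImagesError(ValueError):
    """PSNR is unbounded: the two images are identical (MSE = 0)."""


@dataclass(frozen=True)
class MetricRecord:
    """One metric value with its provenance scope."""

    metric_name: str  # SSIM | PSNR | RMSE | VIF | ...
    value: float
    scope: str = "slice"  # slice | scan | lesion-box


@dataclass(frozen=True)
class CircularROI:
    """Circular in-plane region of interest (voxel units, 0-based center)."""

    slice_index: int
    center: tuple[float, float]  # (row, col)
    radius: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        m = (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= self.radius**2
        if not m.any():
            raise ValueError("empty ROI")
        cr, cc_ = self.center
        if cr - self.radius < -0.5 or cc_ - self.radius < -0.5 \
                or cr + self.radius > shape[0] - 0.5 or cc_ + self.radius > shape[1] - 0.5:
            raise ValueError("ROI extends outside image bounds")
        return m


@dataclass(frozen=True)
class LineSegment:
    """Straight sampling segment in voxel coordinates (row, col)."""

    start: tuple[float, float]
    end: tuple[float, float]
    n_samples: int = 100

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    return a, b


def _gaussian_kernel(sigma: float, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _filter_valid(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Separable 2-D 'valid'-mode correlation with a 1-D kernel."""
    from scipy.ndimage import correlate1d

    out = correlate1d(image, kernel, axis=0, mode="constant")
    out = correlate1d(out, kernel, axis=1, mode="constant")
    r = (kernel.size - 1) // 2
    return out[r:-r, r:-r] if r else out


def ssim(
    test_image: np.ndarray,
    reference_image: np.ndarray,
    data_range: float = DEFAULT_DATA_RANGE,
    window_width: int = 11,
    window_sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Mean structural similarity over the image; symmetric in its arguments."""
    x, y = _check_pair(test_image, reference_image)
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    if window_width % 2 != 1 or window_width < 3:
        raise ValueError("window_width must be an odd integer >= 3")
    radius = (window_width - 1) // 2
    kernel = _gaussian_kernel(window_sigma, radius)
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mx = _filter_valid(x, kernel)
    my = _filter_valid(y, kernel)
    mxx = _filter_valid(x * x, kernel)
    myy = _filter_valid(y * y, kernel)
    mxy = _filter_valid(x * y, kernel)
    vx = mxx - mx * mx
    vy = myy - my * my
    cxy = mxy - mx * my
    num = (2.0 * mx * my + c1) * (2.0 * cxy + c2)
    den = (mx * mx + my * my + c1) * (vx + vy + c2)
    return float(np.mean(num / den))


def psnr(test_image: np.ndarray, reference_image: np.ndarray, data_range: float = DEFAULT_DATA_RANGE) -> float:
    """Peak signal-to-noise ratio in dB: 10 log10(L^2 / MSE) with MSE in HU."""
    x, y = _check_pair(test_image, reference_image)
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        raise IdenticalImagesError("MSE is zero; PSNR has no finite value")
    return float(10.0 * np.log10(data_range**2 / mse))


def rmse_hu(
    test_image: np.ndarray,
    reference_image: np.ndarray,
    selection: np.ndarray | tuple | None = None,
) -> float:
    """Root-mean-squared HU difference, optionally inside a mask or voxel box.

    ``selection`` may be a boolean mask congruent with the images or a
    half-open integer box ``(z0, z1, y0, y1, x0, x1)`` / ``(r0, r1, c0, c1)``.
    """
    x, y = _check_pair(test_image, reference_image)
    if selection is not None:
        if isinstance(selection, np.ndarray):
            if selection.shape != x.shape:
                raise ValueError("mask not congruent with images")
            x, y = x[selection], y[selection]
        else:
            sl = tuple(slice(selection[i], selection[i + 1]) for i in range(0, len(selection), 2))
            x, y = x[sl], y[sl]
    if x.size == 0:
        raise ValueError("empty selection")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def _vif_stats(x: np.ndarray, y: np.ndarray, kernel: np.ndarray):
    mx = _filter_valid(x, kernel)
    my = _filter_valid(y, kernel)
    vx = _filter_valid(x * x, kernel) - mx * mx
    vy = _filter_valid(y * y, kernel) - my * my
    cxy = _filter_valid(x * y, kernel) - mx * my
    return np.maximum(vx, 0.0), np.maximum(vy, 0.0), cxy


def vif(
    test_image: np.ndarray,
    reference_image: np.ndarray,
    n_scales: int = 4,
    sigma_noise_sq: float = 2.0,
    data_range: float = DEFAULT_DATA_RANGE,
) -> float:
    """Pixel-domain multi-scale visual information fidelity.

    The reference is modelled as a Gaussian scale mixture observed through
    additive white Gaussian "neural noise" of variance ``sigma_noise_sq``;
    the score is the ratio of the information the distorted image retains
    about the source to the information the reference carries. 1 for
    identical images; values above 1 indicate contrast enhancement.

    Images are rescaled to a 0-255 convention (from ``data_range``) so the
    standard noise-variance default applies to HU inputs.
    """
    x, y = _check_pair(test_image, reference_image)  # x: distorted/test, y: reference
    if float(np.var(y)) == 0.0:
        raise ZeroVarianceReferenceError("reference image has zero variance")
    rescale = 255.0 / float(data_range)
    x = x * rescale
    y = y * rescale
    eps = 1e-10
    num = 0.0
    den = 0.0
    for scale in range(1, n_scales + 1):
        width = 2 ** (n_scales - scale + 1) + 1   # 17, 9, 5, 3 for four scales
        win = _gaussian_kernel(width / 5.0, (width - 1) // 2)
        if scale > 1:
            # move down the scale-space: blur and decimate by 2
            x = _filter_valid(x, win)[::2, ::2]
            y = _filter_valid(y, win)[::2, ::2]
        if min(x.shape) < width + 2:
            break
        vd, vr, c = _vif_stats(x, y, win)         # distorted var, reference var, covariance
        g = c / (vr + eps)                        # gain of the distortion channel
        sv = vd - g * c                           # variance unexplained by the reference
        sv = np.where(vr < eps, vd, sv)
        g = np.where(vr < eps, 0.0, g)
        vr = np.where(vr < eps, 0.0, vr)
        sv = np.where(vd < eps, 0.0, sv)
        g = np.where(vd < eps, 0.0, g)
        sv = np.where(g < 0.0, vd, sv)
        g = np.maximum(g, 0.0)
        sv = np.maximum(sv, eps)
        num += float(np.sum(np.log10(1.0 + g * g * vr / (sv + sigma_noise_sq))))
        den += float(np.sum(np.log10(1.0 + vr / sigma_noise_sq)))
    if den == 0.0:
        raise ZeroVarianceReferenceError("reference carries no information at any scale")
    return float(num / den)


class ZeroVarianceReferenceError(ValueError):
    """VIF undefined: the reference image is constant."""


def cnr(image: np.ndarray, roi_signal: CircularROI, roi_background: CircularROI) -> float:
    """Contrast-to-noise ratio |mean(signal) - mean(background)| / std(background)."""
    image = np.asarray(image, dtype=float)
    plane_s = image[roi_signal.slice_index] if image.ndim == 3 else image
    plane_b = image[roi_background.slice_index] if image.ndim == 3 else image
    ms = plane_s[roi_signal.mask(plane_s.shape)]
    mb = plane_b[roi_background.mask(plane_b.shape)]
    if roi_signal.slice_index == roi_background.slice_index:
        overlap = roi_signal.mask(plane_s.shape) & roi_background.mask(plane_b.shape)
        if overlap.any():
            raise ValueError("signal and background ROIs overlap")
    sd = float(np.std(mb))
    if sd == 0.0:
        raise ValueError("background ROI has zero standard deviation")
    return float(abs(ms.mean() - mb.mean()) / sd)


def ct_number_deviation(
    test_image: np.ndarray, reference_image: np.ndarray, rois: list[CircularROI]
) -> list[float]:
    """Per ROI, |mean HU(test) - mean HU(reference)|."""
    x, y = _check_pair(test_image, reference_image)
    if not rois:
        raise ValueError("at least one ROI required")
    out = []
    for roi in rois:
        px = x[roi.slice_index] if x.ndim == 3 else x
        py = y[roi.slice_index] if y.ndim == 3 else y
        m = roi.mask(px.shape)
        out.append(float(abs(px[m].mean() - py[m].mean())))
    return out


def line_profile(image: np.ndarray, segment: LineSegment) -> np.ndarray:
    """HU values bilinearly interpolated at evenly spaced points along a segment."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("line_profile expects a 2-D slice")
    for pt in (segment.start, segment.end):
        if not (0 <= pt[0] <= image.shape[0] - 1 and 0 <= pt[1] <= image.shape[1] - 1):
            raise ValueError(f"segment endpoint {pt} outside image bounds")
    t = np.linspace(0.0, 1.0, segment.n_samples)
    rows = segment.start[0] + t * (segment.end[0] - segment.start[0])
    cols = segment.start[1] + t * (segment.end[1] - segment.start[1])
    return map_coordinates(image, np.vstack([rows, cols]), order=1, mode="nearest")


def lesion_metrics(
    denoised_hu: np.ndarray,
    high_hu: np.ndarray,
    lesion_boxes: list,
    data_range: float = DEFAULT_DATA_RANGE,
) -> list[dict]:
    """Per-lesion RMSE (HU) and PSNR (dB) inside each bounding box vs the high-dose volume.

    PSNR is +inf when the two volumes agree exactly inside a box.
    """
    x, y = _check_pair(denoised_hu, high_hu)
    out = []
    for lesion in lesion_boxes:
        box = tuple(lesion.box) if hasattr(lesion, "box") else tuple(lesion)
        r = rmse_hu(x, y, box)
        if r == 0.0:
            p = float("inf")
        else:
            p = float(20.0 * np.log10(data_range) - 20.0 * np.log10(r))
        out.append({"label": getattr(lesion, "label", "lesion"), "rmse_hu": r, "psnr_db": p})
    return out
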