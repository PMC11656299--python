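"""Paired high-/low-dose scan simulation.

A case is simulated by forward-projecting every axial slice of a phantom,
drawing transmitted photon counts at full dose (high-dose scan) and at the
exam type's reduced dose (low-dose scan), and reconstructing both with
filtered back projection. High- and low-dose volumes therefore share the
phantom, organ masks, and lesion annotations but carry independent noise
realizations — the low-dose one with variance larger by roughly 1/d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ldct_benchmark._seeding import rng_from
from ldct_benchmark.sim.geometry import Geometry
from ldct_benchmark.sim.phantom import EXAM_TYPES, ExamTypeError, LesionBox, Phantom, PhantomConfig, make_phantom
from ldct_benchmark.sim.projection import fbp, forward_project, insert_noise, to_hu

#: reduced-dose fractions per exam type
DEFAULT_DOSE_FRACTIONS = {"abdomen": 0.25, "head": 0.25, "chest": 0.10}


@dataclass
class Volume:
    """A reconstructed CT volume in Hounsfield units."""

    hu: np.ndarray  # (z, y, x)
    voxel_spacing: tuple[float, float, float]
    exam_type: str
    patient_id: str
    dose_tag: str  # "high" | "low" | "denoised:<method>"

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        if self.hu.ndim != 3:
            raise ValueError("volume must be 3-D (z, y, x)")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("volume contains non-finite HU values")

    def with_hu(self, hu: np.ndarray, dose_tag: str) -> "Volume":
        return Volume(hu=hu, voxel_spacing=self.voxel_spacing, exam_type=self.exam_type,
                      patient_id=self.patient_id, dose_tag=dose_tag)


@dataclass
class ScanPair:
    """The unit of evaluation: a high-dose volume and its low-dose counterpart."""

    high: Volume
    low: Volume
    organ_masks: dict[str, np.ndarray]
    lesion_boxes: list[LesionBox]
    seed: int

    def __post_init__(self) -> None:
        if self.high.hu.shape != self.low.hu.shape:
            raise ValueError("high and low volumes must share the grid")
        if self.high.patient_id != self.low.patient_id:
            raise ValueError("high and low volumes must share patient identity")

    @property
    def exam_type(self) -> str:
        return self.high.exam_type

    @property
    def patient_id(self) -> str:
        return self.high.patient_id


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters: phantom, acquisition, and reconstruction."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    n_angles: int = 512
    photons_per_ray: float = 1e5
    filter_name: str = "hann"
    dose_fractions: dict = field(default_factory=lambda: dict(DEFAULT_DOSE_FRACTIONS))

    def geometry(self) -> Geometry:
        return Geometry.standard(
            image_size=self.phantom.image_size, fov=self.phantom.fov, n_angles=self.n_angles
        )

    @classmethod
    def desk(cls) -> "SimConfig":
        """Small, minutes-scale configuration used by the test-bench examples."""
        return cls(
            phantom=PhantomConfig(image_size=128, fov=350.0, n_slices_range=(3, 5)),
            n_angles=192,
        )


def reconstruct_volume(
    phantom: Phantom,
    config: SimConfig,
    dose_fraction: float,
    noise_rng: np.random.Generator | None,
    dose_tag: str,
) -> Volume:
    """Project, optionally add counting noise at ``dose_fraction``, and reconstruct."""
    geom = config.geometry()
    slices = []
    for z in range(phantom.n_slices):
        sino = forward_project(phantom.attenuation_map[z], geom)
        if noise_rng is not None:
            sino = insert_noise(sino, dose_fraction, config.photons_per_ray, noise_rng)
        mu = fbp(sino, config.filter_name)
        slices.append(to_hu(mu, config.phantom.mu_water))
    return Volume(
        hu=np.stack(slices),
        voxel_spacing=phantom.voxel_spacing,
        exam_type=phantom.exam_type,
        patient_id=phantom.patient_id,
        dose_tag=dose_tag,
    )


def simulate_case(
    exam_type: str,
    seed: int,
    dose_fraction: float | None = None,
    config: SimConfig | None = None,
    patient_id: str | None = None,
) -> ScanPair:
    """Simulate one paired high-/low-dose case.

    The default dose fraction is 0.25 for abdomen and head and 0.10 for
    chest. The high-dose scan is acquired at the full photon budget (it is
    slightly noisy, mirroring routine-dose acquisitions), the low-dose scan
    at ``dose_fraction`` of it. Bit-reproducible for a fixed seed and
    configuration.
    """
    if exam_type not in EXAM_TYPES:
        raise ExamTypeError(f"unknown exam type {exam_type!r}; expected one of {EXAM_TYPES}")
    cfg = config or SimConfig()
    d = cfg.dose_fractions[exam_type] if dose_fraction is None else float(dose_fraction)
    if not (0.0 < d <= 1.0):
        raise ValueError("dose_fraction must lie in (0, 1]")
    phantom = make_phantom(exam_type, seed, cfg.phantom, patient_id=patient_id)
    hd_rng = rng_from(seed, 1)
    ld_rng = rng_from(seed, 2)
    high = reconstruct_volume(phantom, cfg, 1.0, hd_rng, "high")
    low = reconstruct_volume(phantom, cfg, d, ld_rng, "low")
    return ScanPair(
        high=high,
        low=low,
        organ_masks=phantom.organ_masks,
        lesion_boxes=phantom.lesion_boxes,
        seed=int(seed),
    )
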