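"""Parametric anthropomorphic phantoms for the three exam types.

Each phantom is a small 3-D stack of axial slices built from analytic
ellipses: an elliptical body of soft tissue, the exam type's organ (liver
for abdomen, brain for head, two lungs for chest), a bone structure (skull
rim for head, vertebral body otherwise), and at least one low-contrast
ellipsoidal lesion placed fully inside the organ. Sizes, positions, and
tissue values are jittered deterministically from an integer seed, so the
same seed and configuration always produce a bit-identical phantom.

Coordinates follow radiological convention for the reconstruction grid:
array axes are (slice z, row y, column x); in-plane physical coordinates
are centered at the image center with x rightwards and y upwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ldct_benchmark._seeding import rng_from

EXAM_TYPES = ("abdomen", "head", "chest")
ORGAN_FOR_EXAM = {"abdomen": "liver", "head": "brain", "chest": "lung"}


class ExamTypeError(ValueError):
    """Unknown exam type."""


class PhantomError(ValueError):
    """Phantom invariant violated."""


@dataclass(frozen=True)
class TissueSpec:
    """Nominal Hounsfield value and uniform jitter half-width for a tissue."""

    hu: float
    jitter: float = 0.0


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and tissue parameters of the phantom generator.

    Linear sizes are millimetres; the in-plane grid is ``image_size`` voxels
    across a square ``fov``. Jitters are uniform half-widths applied
    per-phantom (one draw per scan, not per voxel).
    """

    image_size: int = 256
    fov: float = 350.0
    slice_thickness: float = 3.0
    n_slices_range: tuple[int, int] = (8, 32)
    mu_water: float = 0.02  # 1/mm

    soft_tissue: TissueSpec = TissueSpec(35.0, 5.0)
    liver: TissueSpec = TissueSpec(55.0, 5.0)
    brain: TissueSpec = TissueSpec(40.0, 3.0)
    lung: TissueSpec = TissueSpec(-700.0, 30.0)
    bone: TissueSpec = TissueSpec(700.0, 50.0)
    lesion_contrast: TissueSpec = TissueSpec(-30.0, 8.0)  # relative to host organ; lungs use a nodule instead
    lung_nodule: TissueSpec = TissueSpec(-150.0, 30.0)

    # body semi-axes (x, y) and relative jitter
    body_axes: dict = field(
        default_factory=lambda: {
            "abdomen": (150.0, 100.0),
            "head": (80.0, 100.0),
            "chest": (155.0, 105.0),
        }
    )
    axis_jitter_frac: float = 0.08
    organ_frac: dict = field(
        default_factory=lambda: {
            "liver": (0.38, 0.42),  # semi-axes as fraction of body semi-axes
            "brain": (0.80, 0.84),
            "lung": (0.34, 0.62),
        }
    )
    skull_thickness: float = 7.0
    lesion_radius_range: tuple[float, float] = (5.0, 10.0)

    @property
    def pixel_spacing(self) -> float:
        return self.fov / self.image_size

    def hu_to_mu(self, hu: float | np.ndarray) -> float | np.ndarray:
        """Hounsfield -> linear attenuation (1/mm), clipped at vacuum."""
        return np.maximum(self.mu_water * (1.0 + np.asarray(hu) / 1000.0), 0.0)


@dataclass
class LesionBox:
    """Axis-aligned voxel box (0-based, half-open) with a lesion label."""

    label: str
    box: tuple[int, int, int, int, int, int]  # z0, z1, y0, y1, x0, x1


@dataclass
class Phantom:
    attenuation_map: np.ndarray  # (z, y, x), 1/mm
    voxel_spacing: tuple[float, float, float]  # mm (dz, dy, dx)
    organ_masks: dict[str, np.ndarray]
    lesion_boxes: list[LesionBox]
    exam_type: str
    patient_id: str
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.attenuation_map < 0):
            raise PhantomError("attenuation must be non-negative")
        body = self.organ_masks.get("body")
        if body is None:
            raise PhantomError("phantom requires a body mask")
        for name, mask in self.organ_masks.items():
            if mask.shape != self.attenuation_map.shape:
                raise PhantomError(f"mask {name!r} not congruent with attenuation map")
            if name != "body" and np.any(mask & ~body):
                raise PhantomError(f"organ mask {name!r} extends outside the body")
        organ = ORGAN_FOR_EXAM[self.exam_type]
        for lesion in self.lesion_boxes:
            z0, z1, y0, y1, x0, x1 = lesion.box
            if not (0 <= z0 < z1 and 0 <= y0 < y1 and 0 <= x0 < x1):
                raise PhantomError(f"degenerate lesion box {lesion.box}")
            if not np.all(self.organ_masks[organ][z0:z1, y0:y1, x0:x1]):
                raise PhantomError(f"lesion box {lesion.box} not contained in {organ!r} mask")

    @property
    def n_slices(self) -> int:
        return int(self.attenuation_map.shape[0])


def _ellipse_mask(cfg: PhantomConfig, cx: float, cy: float, ax: float, ay: float) -> np.ndarray:
    """Boolean in-plane mask of an axis-aligned ellipse given in mm."""
    n = cfg.image_size
    h = cfg.pixel_spacing
    c = (n - 1) / 2.0
    idx = np.arange(n, dtype=float)
    x = (idx - c) * h
    y = (c - idx) * h
    xx, yy = np.meshgrid(x, y)
    if ax <= 0 or ay <= 0:
        return np.zeros((n, n), dtype=bool)
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def _taper(z: int, n_slices: int, z0: float, z1: float) -> float:
    """Semi-elliptical axial profile in (0, 1]; zero outside [z0, z1]."""
    zc = 0.5 * (z0 + z1)
    zr = 0.5 * (z1 - z0)
    if zr <= 0:  # single-slice organ: present exactly at its center slice
        return 1.0 if abs(z - zc) < 0.5 else 0.0
    u = (z - zc) / zr
    return float(np.sqrt(max(0.0, 1.0 - u * u)))


def make_phantom(
    exam_type: str,
    seed: int,
    config: PhantomConfig | None = None,
    patient_id: str | None = None,
) -> Phantom:
    """Build a randomized phantom for one exam type.

    The organ matches the exam type (abdomen -> liver, head -> brain,
    chest -> two lungs), the head carries a bone rim, and at least one
    low-contrast lesion lies entirely inside the organ mask. All random
    choices derive from ``seed``.
    """
    if exam_type not in EXAM_TYPES:
        raise ExamTypeError(f"unknown exam type {exam_type!r}; expected one of {EXAM_TYPES}")
    cfg = config or PhantomConfig()
    rng = rng_from(seed, 101)
    n = cfg.image_size
    lo, hi = cfg.n_slices_range
    n_slices = int(rng.integers(lo, hi + 1))

    def draw(t: TissueSpec) -> float:
        return float(t.hu + rng.uniform(-t.jitter, t.jitter))

    jit = cfg.axis_jitter_frac
    bx0, by0 = cfg.body_axes[exam_type]
    bx = bx0 * (1.0 + rng.uniform(-jit, jit))
    by = by0 * (1.0 + rng.uniform(-jit, jit))

    soft_hu = draw(cfg.soft_tissue)
    bone_hu = draw(cfg.bone)
    hu = np.full((n_slices, n, n), -1000.0)
    body = np.zeros((n_slices, n, n), dtype=bool)
    organ_name = ORGAN_FOR_EXAM[exam_type]
    organ = np.zeros((n_slices, n, n), dtype=bool)

    # organ axial extent: central ~80% of the stack so some end slices lack it;
    # the minimum half-extent keeps the organ present in very short stacks
    _zc = 0.5 * (n_slices - 1)
    _zr = max(0.4 * (n_slices - 1), 0.75)
    oz0 = _zc - _zr
    oz1 = _zc + _zr

    if exam_type == "chest":
        organ_hu = draw(cfg.lung)
    elif exam_type == "abdomen":
        organ_hu = draw(cfg.liver)
    else:
        organ_hu = draw(cfg.brain)
    fx, fy = cfg.organ_frac[organ_name]
    fx *= 1.0 + rng.uniform(-jit, jit)
    fy *= 1.0 + rng.uniform(-jit, jit)
    # organ center offset as fraction of body semi-axes
    if exam_type == "abdomen":
        ocx, ocy = -0.30 * bx, 0.10 * by
    elif exam_type == "chest":
        ocx, ocy = 0.42 * bx, 0.05 * by  # per-lung centers at +/- ocx
    else:
        ocx, ocy = 0.0, 0.0
    ocx += rng.uniform(-5.0, 5.0)
    ocy += rng.uniform(-5.0, 5.0)

    for z in range(n_slices):
        bt = 0.9 + 0.1 * _taper(z, n_slices, -0.5, n_slices - 0.5)
        body_sl = _ellipse_mask(cfg, 0.0, 0.0, bx * bt, by * bt)
        body[z] = body_sl
        hu[z][body_sl] = soft_hu
        ot = _taper(z, n_slices, oz0, oz1)
        if ot > 0.15:
            if exam_type == "chest":
                left = _ellipse_mask(cfg, -ocx, ocy, fx * bx * ot, fy * by * ot)
                right = _ellipse_mask(cfg, ocx, ocy, fx * bx * ot, fy * by * ot)
                organ_sl = (left | right) & body_sl
            else:
                organ_sl = _ellipse_mask(cfg, ocx, ocy, fx * bx * ot, fy * by * ot) & body_sl
            organ[z] = organ_sl
            hu[z][organ_sl] = organ_hu
        if exam_type == "head":
            rim_out = _ellipse_mask(cfg, 0.0, 0.0, bx * bt, by * bt)
            rim_in = _ellipse_mask(cfg, 0.0, 0.0, bx * bt - cfg.skull_thickness, by * bt - cfg.skull_thickness)
            hu[z][rim_out & ~rim_in] = bone_hu
            organ[z] &= rim_in
            hu[z][organ[z]] = organ_hu
        else:
            # vertebral body, posterior midline, outside the organ
            vert = _ellipse_mask(cfg, 0.0, -0.75 * by, 16.0, 16.0) & body_sl & ~organ[z]
            hu[z][vert] = bone_hu

    # ---- lesion: ellipsoid fully inside the organ mask -------------------
    if exam_type == "chest":
        lesion_hu = draw(cfg.lung_nodule)
    else:
        lesion_hu = organ_hu + draw(cfg.lesion_contrast)
    h = cfg.pixel_spacing
    r_mm = float(rng.uniform(*cfg.lesion_radius_range))
    # center the lesion near the organ's densest slice, offset within the organ
    zc = int(round(0.5 * (oz0 + oz1)))
    if exam_type == "chest":
        lcx, lcy = ocx, ocy  # inside the right lung
    else:
        lcx, lcy = ocx, ocy
    lcx += rng.uniform(-0.15, 0.15) * fx * bx
    lcy += rng.uniform(-0.15, 0.15) * fy * by
    boxes: list[LesionBox] = []
    c = (n - 1) / 2.0
    for _ in range(12):
        zr = max(0, int(round(r_mm / cfg.slice_thickness)) - 1)
        x0 = int(np.floor(c + (lcx - r_mm) / h))
        x1 = int(np.ceil(c + (lcx + r_mm) / h)) + 1
        y0 = int(np.floor(c - (lcy + r_mm) / h))
        y1 = int(np.ceil(c - (lcy - r_mm) / h)) + 1
        if 0 <= y0 < y1 <= n and 0 <= x0 < x1 <= n:
            # keep only the contiguous slab around zc whose slices fully contain the box
            ok = np.array([bool(np.all(organ[z, y0:y1, x0:x1])) for z in range(n_slices)])
            if ok.any():
                anchor = int(np.argmin([abs(z - zc) if ok[z] else 10**6 for z in range(n_slices)]))
                if ok[anchor]:
                    z0 = anchor
                    while z0 > 0 and ok[z0 - 1] and anchor - (z0 - 1) <= zr:
                        z0 -= 1
                    z1 = anchor + 1
                    while z1 < n_slices and ok[z1] and z1 - anchor <= zr:
                        z1 += 1
                    boxes.append(LesionBox(label="lesion-0", box=(z0, z1, y0, y1, x0, x1)))
                    break
        r_mm *= 0.8
    if not boxes:
        # deterministic fallback: the deepest interior point of the organ
        from scipy.ndimage import distance_transform_edt

        zc = int(np.argmax(organ.sum(axis=(1, 2))))
        if not organ[zc].any():
            raise PhantomError("organ mask is empty; cannot place a lesion")
        dist = distance_transform_edt(organ[zc])
        cy_i, cx_i = np.unravel_index(int(np.argmax(dist)), dist.shape)
        for half in (3, 2, 1):
            box = (zc, zc + 1, cy_i - half, cy_i + half + 1, cx_i - half, cx_i + half + 1)
            inside_grid = 0 <= box[2] < box[3] <= n and 0 <= box[4] < box[5] <= n
            if inside_grid and np.all(organ[box[0] : box[1], box[2] : box[3], box[4] : box[5]]):
                boxes.append(LesionBox(label="lesion-0", box=box))
                break
        else:
            raise PhantomError("could not place a lesion inside the organ")

    z0, z1, y0, y1, x0, x1 = boxes[0].box
    # paint an ellipsoid inscribed in the box
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1, dtype=float), np.arange(y0, y1, dtype=float), np.arange(x0, x1, dtype=float), indexing="ij"
    )
    czc, cyc, cxc = (z0 + z1 - 1) / 2.0, (y0 + y1 - 1) / 2.0, (x0 + x1 - 1) / 2.0
    rz = max((z1 - z0) / 2.0, 0.5)
    ry = max((y1 - y0) / 2.0, 0.5)
    rx_v = max((x1 - x0) / 2.0, 0.5)
    inside = ((zz - czc) / rz) ** 2 + ((yy - cyc) / ry) ** 2 + ((xx - cxc) / rx_v) ** 2 <= 1.0
    region = hu[z0:z1, y0:y1, x0:x1]
    region[inside] = lesion_hu
    hu[z0:z1, y0:y1, x0:x1] = region

    masks = {"body": body, organ_name: organ}
    if exam_type == "abdomen":
        masks["lung"] = np.zeros_like(body)  # abdomen carries an (empty) lung mask for slice filtering
    return Phantom(
        attenuation_map=np.asarray(cfg.hu_to_mu(hu)),
        voxel_spacing=(cfg.slice_thickness, h, h),
        organ_masks=masks,
        lesion_boxes=boxes,
        exam_type=exam_type,
        patient_id=patient_id or f"{exam_type}-{seed:08d}",
        seed=int(seed),
    )
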