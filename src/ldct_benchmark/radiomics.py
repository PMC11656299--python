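"""Radiomic feature extraction and radiomic feature similarity (RFS).

Features are computed on HU values inside an organ mask: first-order
statistics on the raw values, plus gray-level co-occurrence (GLCM) and
gray-level run-length (GLRLM) texture families on values discretized at a
fixed bin width (default 25 HU, bins anchored at the masked minimum). 3-D
texture matrices aggregate over the 13 unique voxel directions; shape
features are deliberately absent because every algorithm is evaluated
inside the same high-dose segmentation mask.

The RFS of algorithm i on scan s is the cosine similarity between the
min-max-normalized feature vector of algorithm i and that of the high-dose
scan (algorithm index 0). Normalization subtracts the per-feature maximum
over algorithms and divides by the per-feature range, mapping every value
into [-1, 0]; features constant across algorithms are dropped. A
conventional variant mapping into [0, 1] (subtracting the minimum) is
available via ``variant="minmax"`` but is not the default.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RadiomicsConfig",
    "FeatureVector",
    "FeatureMatrix",
    "RFSRecord",
    "extract_features",
    "normalize_features",
    "rfs",
    "rfs_summary",
    "DIRECTIONS_3D",
]

#: the 13 unique 3-D neighbor directions (up to sign), (dz, dy, dx)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


class EmptyMaskError(ValueError):
    """Feature extraction requires a non-empty mask."""


class DegenerateFeaturesError(ValueError):
    """All features constant across algorithms; RFS undefined."""


class ZeroNormRowError(ValueError):
    """A normalized feature vector has zero norm; cosine undefined."""


@dataclass(frozen=True)
class RadiomicsConfig:
    """Discretization and texture settings for feature extraction."""

    bin_width: float = 25.0  # HU
    glcm_distance: int = 1
    directions: tuple = DIRECTIONS_3D

    def fingerprint(self) -> str:
        payload = f"{self.bin_width}:{self.glcm_distance}:{self.directions}"
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class FeatureVector:
    """Ordered feature values for one (scan, algorithm) pair."""

    scan_id: str
    algorithm_index: int  # 0 = high dose
    values: dict[str, float]
    extraction_fingerprint: str = ""


@dataclass
class FeatureMatrix:
    """Per-scan matrix R[i, j]: rows = algorithms (0 = high dose), columns = features."""

    scan_id: str
    algorithm_indices: list[int]
    feature_names: list[str]
    values: np.ndarray  # (n_algorithms, n_features)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if 0 not in self.algorithm_indices:
            raise ValueError("feature matrix requires the high-dose row (algorithm index 0)")
        if self.values.shape != (len(self.algorithm_indices), len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @classmethod
    def from_vectors(cls, vectors: list[FeatureVector]) -> "FeatureMatrix":
        if not vectors:
            raise ValueError("no feature vectors")
        names = list(vectors[0].values.keys())
        for v in vectors[1:]:
            if list(v.values.keys()) != names:
                raise ValueError("feature name sets differ across algorithms")
        order = sorted(range(len(vectors)), key=lambda k: vectors[k].algorithm_index)
        return cls(
            scan_id=vectors[0].scan_id,
            algorithm_indices=[vectors[k].algorithm_index for k in order],
            feature_names=names,
            values=np.array([[vectors[k].values[n] for n in names] for k in order]),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "algorithm", self.algorithm_indices)
        df.insert(0, "scan_id", self.scan_id)
        return df


@dataclass(frozen=True)
class RFSRecord:
    scan_id: str
    algorithm_index: int
    rfs: float

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.rfs <= 1.0 + 1e-9):
            raise ValueError(f"RFS {self.rfs} outside [-1, 1]")


# --------------------------------------------------------------------------
# feature extraction
# --------------------------------------------------------------------------

def _discretize(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width discretization to levels 1..Ng, anchored at the minimum."""
    levels = np.floor((values - values.min()) / bin_width).astype(np.int64) + 1
    return levels


def _first_order(values: np.ndarray, bin_width: float) -> dict[str, float]:
    v = values
    n = v.size
    mean = float(v.mean())
    p10, p25, p50, p75, p90 = (float(np.percentile(v, q)) for q in (10, 25, 50, 75, 90))
    hist = np.bincount(_discretize(v, bin_width))
    p = hist[hist > 0] / n
    mid = v[(v >= p10) & (v <= p90)]
    centered = v - mean
    var = float(np.mean(centered**2))
    sd = np.sqrt(var)
    return {
        "firstorder_mean": mean,
        "firstorder_median": p50,
        "firstorder_minimum": float(v.min()),
        "firstorder_maximum": float(v.max()),
        "firstorder_range": float(v.max() - v.min()),
        "firstorder_p10": p10,
        "firstorder_p90": p90,
        "firstorder_iqr": p75 - p25,
        "firstorder_variance": var,
        "firstorder_skewness": float(np.mean(centered**3) / sd**3) if sd > 0 else 0.0,
        "firstorder_kurtosis": float(np.mean(centered**4) / var**2) if var > 0 else 0.0,
        "firstorder_mad": float(np.mean(np.abs(centered))),
        "firstorder_rmad": float(np.mean(np.abs(mid - mid.mean()))) if mid.size else 0.0,
        "firstorder_energy": float(np.sum(v.astype(float) ** 2)),
        "firstorder_rms": float(np.sqrt(np.mean(v.astype(float) ** 2))),
        "firstorder_entropy": float(-np.sum(p * np.log2(p))),
        "firstorder_uniformity": float(np.sum(p**2)),
    }


def glcm_counts(
    levels: np.ndarray, mask: np.ndarray, direction: tuple[int, int, int], distance: int = 1
) -> np.ndarray:
    """Symmetric co-occurrence counts between in-mask voxel pairs at one offset."""
    ng = int(levels[mask].max())
    counts = np.zeros((ng, ng), dtype=float)
    d = tuple(distance * np.asarray(direction))
    src = tuple(slice(max(0, -dd), levels.shape[k] - max(0, dd)) for k, dd in enumerate(d))
    dst = tuple(slice(max(0, dd), levels.shape[k] + min(0, dd)) for k, dd in enumerate(d))
    valid = mask[src] & mask[dst]
    if valid.any():
        a = levels[src][valid] - 1
        b = levels[dst][valid] - 1
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)
    return counts


def _glcm_features(levels: np.ndarray, mask: np.ndarray, cfg: RadiomicsConfig) -> dict[str, float]:
    ng = int(levels[mask].max())
    i_idx, j_idx = np.meshgrid(np.arange(1, ng + 1), np.arange(1, ng + 1), indexing="ij")
    feats: dict[str, list[float]] = {}
    for direction in cfg.directions:
        counts = glcm_counts(levels, mask, direction, cfg.glcm_distance)
        total = counts.sum()
        if total == 0:
            continue
        p = counts / total
        px = p.sum(axis=1)
        mu_i = float(np.sum(i_idx * p))
        mu_j = float(np.sum(j_idx * p))
        sd_i = np.sqrt(np.sum((i_idx - mu_i) ** 2 * p))
        diff = np.abs(i_idx - j_idx)
        nz = p > 0
        vals = {
            "glcm_contrast": float(np.sum(p * (i_idx - j_idx) ** 2)),
            "glcm_dissimilarity": float(np.sum(p * diff)),
            "glcm_inverse_difference": float(np.sum(p / (1.0 + diff))),
            "glcm_idm": float(np.sum(p / (1.0 + diff**2))),
            "glcm_asm": float(np.sum(p**2)),
            "glcm_joint_entropy": float(-np.sum(p[nz] * np.log2(p[nz]))),
            "glcm_max_probability": float(p.max()),
            "glcm_joint_average": mu_i,
            "glcm_autocorrelation": float(np.sum(i_idx * j_idx * p)),
            "glcm_cluster_shade": float(np.sum((i_idx + j_idx - mu_i - mu_j) ** 3 * p)),
            "glcm_cluster_prominence": float(np.sum((i_idx + j_idx - mu_i - mu_j) ** 4 * p)),
            "glcm_correlation": (
                float(np.sum((i_idx - mu_i) * (j_idx - mu_j) * p) / sd_i**2) if sd_i > 0 else 1.0
            ),
        }
        for k, val in vals.items():
            feats.setdefault(k, []).append(val)
    return {k: float(np.mean(v)) for k, v in feats.items()}


def glrlm_counts(levels: np.ndarray, mask: np.ndarray, direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length counts P[g-1, r-1] for one direction; out-of-mask voxels break runs."""
    ng = int(levels[mask].max())
    shape = levels.shape
    d = np.asarray(direction)
    lab = np.where(mask, levels, 0)
    # run starts: in-mask voxels whose predecessor along -d is absent or different
    prev = np.zeros_like(lab)
    src = tuple(slice(max(0, dd), shape[k] + min(0, dd)) for k, dd in enumerate(d))
    dst = tuple(slice(max(0, -dd), shape[k] - max(0, dd)) for k, dd in enumerate(d))
    prev[src] = lab[dst]
    starts = np.argwhere((lab > 0) & (lab != prev))
    max_run = int(np.ceil(np.linalg.norm(shape)))
    counts = np.zeros((ng, max_run), dtype=float)
    for z, y, x in starts:
        g = lab[z, y, x]
        run = 1
        zz, yy, xx = z + d[0], y + d[1], x + d[2]
        while 0 <= zz < shape[0] and 0 <= yy < shape[1] and 0 <= xx < shape[2] and lab[zz, yy, xx] == g:
            run += 1
            zz += d[0]
            yy += d[1]
            xx += d[2]
        counts[g - 1, min(run, max_run) - 1] += 1.0
    return counts[:, : max(1, int(np.max(np.nonzero(counts.sum(axis=0))[0], initial=0)) + 1)]


def _glrlm_features(levels: np.ndarray, mask: np.ndarray, cfg: RadiomicsConfig) -> dict[str, float]:
    n_voxels = int(mask.sum())
    feats: dict[str, list[float]] = {}
    for direction in cfg.directions:
        p = glrlm_counts(levels, mask, direction)
        nr = p.sum()
        if nr == 0:
            continue
        g = np.arange(1, p.shape[0] + 1)[:, None].astype(float)
        r = np.arange(1, p.shape[1] + 1)[None, :].astype(float)
        pg = p.sum(axis=1)
        pr = p.sum(axis=0)
        mu_r = float(np.sum(p * r) / nr)
        mu_g = float(np.sum(p * g) / nr)
        nzp = p > 0
        pn = p / nr
        vals = {
            "glrlm_sre": float(np.sum(pr / np.arange(1, pr.size + 1) ** 2) / nr),
            "glrlm_lre": float(np.sum(pr * np.arange(1, pr.size + 1) ** 2) / nr),
            "glrlm_gln": float(np.sum(pg**2) / nr),
            "glrlm_rln": float(np.sum(pr**2) / nr),
            "glrlm_run_percentage": float(nr / n_voxels),
            "glrlm_lglre": float(np.sum(pg / np.arange(1, pg.size + 1) ** 2) / nr),
            "glrlm_hglre": float(np.sum(pg * np.arange(1, pg.size + 1) ** 2) / nr),
            "glrlm_srlgle": float(np.sum(p / (g**2 * r**2)) / nr),
            "glrlm_srhgle": float(np.sum(p * g**2 / r**2) / nr),
            "glrlm_lrlgle": float(np.sum(p * r**2 / g**2) / nr),
            "glrlm_lrhgle": float(np.sum(p * g**2 * r**2) / nr),
            "glrlm_glv": float(np.sum(pn * (g - mu_g) ** 2)),
            "glrlm_rlv": float(np.sum(pn * (r - mu_r) ** 2)),
            "glrlm_run_entropy": float(-np.sum(pn[nzp] * np.log2(pn[nzp]))),
        }
        for k, val in vals.items():
            feats.setdefault(k, []).append(val)
    return {k: float(np.mean(v)) for k, v in feats.items()}


def extract_features(
    volume_hu: np.ndarray,
    organ_mask: np.ndarray,
    config: RadiomicsConfig | None = None,
    scan_id: str = "",
    algorithm_index: int = 0,
) -> FeatureVector:
    """Extract the fixed first-order + GLCM + GLRLM feature set inside a mask.

    Accepts 2-D or 3-D arrays; 2-D inputs are treated as single-slice
    volumes (in-plane texture directions only contribute pairs).
    """
    cfg = config or RadiomicsConfig()
    hu = np.asarray(volume_hu, dtype=float)
    mask = np.asarray(organ_mask, dtype=bool)
    if hu.shape != mask.shape:
        raise ValueError("mask not congruent with volume")
    if hu.ndim == 2:
        hu = hu[None]
        mask = mask[None]
    if hu.ndim != 3:
        raise ValueError("volume must be 2-D or 3-D")
    if not mask.any():
        raise EmptyMaskError("organ mask is empty")
    values = hu[mask]
    feats = _first_order(values, cfg.bin_width)
    levels = np.zeros(hu.shape, dtype=np.int64)
    levels[mask] = _discretize(values, cfg.bin_width)
    feats.update(_glcm_features(levels, mask, cfg))
    feats.update(_glrlm_features(levels, mask, cfg))
    return FeatureVector(
        scan_id=scan_id,
        algorithm_index=algorithm_index,
        values=feats,
        extraction_fingerprint=cfg.fingerprint(),
    )


# --------------------------------------------------------------------------
# normalization and similarity
# --------------------------------------------------------------------------

def normalize_features(matrix: FeatureMatrix, variant: str = "paper") -> FeatureMatrix:
    """Min-max normalize each feature across algorithms; drop constant features.

    ``variant="paper"`` maps each feature to [-1, 0] by subtracting the
    per-feature maximum before dividing by the range; ``variant="minmax"``
    subtracts the minimum instead, mapping to [0, 1].
    """
    if len(matrix.algorithm_indices) < 2:
        raise ValueError("normalization requires at least 2 algorithms (high dose + 1)")
    if variant not in ("paper", "minmax"):
        raise ValueError(f"unknown variant {variant!r}")
    vals = matrix.values
    top = vals.max(axis=0)
    bottom = vals.min(axis=0)
    spread = top - bottom
    keep = spread > 0
    if not keep.any():
        raise DegenerateFeaturesError("all features are constant across algorithms")
    ref = top if variant == "paper" else bottom
    normalized = (vals[:, keep] - ref[keep]) / spread[keep]
    return FeatureMatrix(
        scan_id=matrix.scan_id,
        algorithm_indices=list(matrix.algorithm_indices),
        feature_names=[n for n, k in zip(matrix.feature_names, keep) if k],
        values=normalized,
    )


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    nx = float(np.linalg.norm(x))
    ny = float(np.linalg.norm(y))
    if nx == 0.0 or ny == 0.0:
        raise ZeroNormRowError("cosine similarity undefined for zero-norm vector")
    return float(np.dot(x, y) / (nx * ny))


def rfs(matrix: FeatureMatrix, normalized: bool = False, variant: str = "paper") -> list[RFSRecord]:
    """Radiomic feature similarity of every algorithm against the high-dose row."""
    m = matrix if normalized else normalize_features(matrix, variant)
    hd_row = m.values[m.algorithm_indices.index(0)]
    out = []
    for pos, idx in enumerate(m.algorithm_indices):
        if idx == 0:
            continue
        out.append(RFSRecord(scan_id=m.scan_id, algorithm_index=idx,
                             rfs=cosine_similarity(m.values[pos], hd_row)))
    return out


def rfs_summary(records: pd.DataFrame | list[dict], by: tuple[str, ...] = ("method", "exam_type")) -> pd.DataFrame:
    """Mean RFS per group: average over scans within each seed, then mean +/- std over seeds.

    ``records`` needs columns {method, exam_type, seed, scan_id, rfs}. With a
    single seed the spread is reported as 0 and flagged in ``single_seed``.
    """
    df = pd.DataFrame(records)
    required = set(by) | {"seed", "rfs"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError("empty record set")
    per_seed = df.groupby([*by, "seed"], sort=True)["rfs"].mean().reset_index()
    agg = per_seed.groupby(list(by), sort=True)["rfs"].agg(["mean", "std", "count"]).reset_index()
    agg["single_seed"] = agg["count"] == 1
    agg["std"] = agg["std"].fillna(0.0)
    return agg.rename(columns={"mean": "rfs_mean", "std": "rfs_std", "count": "n_seeds"})
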