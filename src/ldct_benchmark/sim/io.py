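"""Volume and dataset I/O.

Volumes are written either as NIfTI (via nibabel) or as a raw little-endian
float32 array with a JSON sidecar carrying shape, voxel spacing, dose tag,
exam type, and patient id. A dataset manifest is a JSON file listing scans
with file paths, exam types, patient ids, and lesion boxes (voxel
coordinates, 0-based, half-open). An optional DICOM series reader covers
real data when pydicom is available.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from ldct_benchmark.sim.case import ScanPair, Volume
from ldct_benchmark.sim.phantom import LesionBox

MANIFEST_VERSION = 1


class ManifestError(ValueError):
    """Malformed or version-incompatible dataset manifest."""


def write_volume_nifti(volume: Volume, path: str | Path) -> Path:
    path = Path(path)
    dz, dy, dx = volume.voxel_spacing
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(np.asarray(volume.hu, dtype=np.float32).transpose(2, 1, 0), affine)
    img.header.set_zooms((dx, dy, dz))
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else Path(str(path) + ".json")
    sidecar.write_text(json.dumps(_volume_meta(volume)))
    return path


def read_volume_nifti(path: str | Path) -> Volume:
    path = Path(path)
    img = nib.load(str(path))
    meta = json.loads(Path(str(path) + ".json").read_text())
    hu = np.asanyarray(img.dataobj, dtype=np.float32).transpose(2, 1, 0).astype(float)
    return Volume(hu=hu, voxel_spacing=tuple(meta["voxel_spacing"]), exam_type=meta["exam_type"],
                  patient_id=meta["patient_id"], dose_tag=meta["dose_tag"])


def _volume_meta(volume: Volume) -> dict:
    return {
        "shape": list(volume.hu.shape),
        "voxel_spacing": list(volume.voxel_spacing),
        "exam_type": volume.exam_type,
        "patient_id": volume.patient_id,
        "dose_tag": volume.dose_tag,
        "dtype": "<f4",
    }


def write_volume_raw(volume: Volume, path: str | Path) -> Path:
    """Raw little-endian float32 voxels + JSON sidecar (``<path>.json``)."""
    path = Path(path)
    np.asarray(volume.hu, dtype="<f4").tofile(path)
    Path(str(path) + ".json").write_text(json.dumps(_volume_meta(volume)))
    return path


def read_volume_raw(path: str | Path) -> Volume:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    hu = np.fromfile(path, dtype="<f4").reshape(meta["shape"]).astype(float)
    return Volume(hu=hu, voxel_spacing=tuple(meta["voxel_spacing"]), exam_type=meta["exam_type"],
                  patient_id=meta["patient_id"], dose_tag=meta["dose_tag"])


def read_dicom_series(directory: str | Path) -> Volume:
    """Read a single-series DICOM directory into a HU volume (requires pydicom)."""
    import pydicom

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no .dcm files in {directory}")
    datasets = [pydicom.dcmread(str(f)) for f in files]
    datasets.sort(key=lambda d: float(getattr(d, "ImagePositionPatient", [0, 0, 0])[2]))
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    first = datasets[0]
    dy, dx = (float(v) for v in getattr(first, "PixelSpacing", [1.0, 1.0]))
    dz = float(getattr(first, "SliceThickness", 1.0))
    return Volume(hu=np.stack(slices), voxel_spacing=(dz, dy, dx),
                  exam_type=str(getattr(first, "BodyPartExamined", "unknown")).lower(),
                  patient_id=str(getattr(first, "PatientID", "unknown")), dose_tag="high")


def save_scan_pair(pair: ScanPair, directory: str | Path, fmt: str = "raw") -> dict:
    """Write one pair plus masks; return its manifest entry."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    writer = write_volume_raw if fmt == "raw" else write_volume_nifti
    ext = ".raw" if fmt == "raw" else ".nii"
    entry: dict = {
        "patient_id": pair.patient_id,
        "exam_type": pair.exam_type,
        "seed": pair.seed,
        "format": fmt,
        "lesion_boxes": [{"label": b.label, "box": list(b.box)} for b in pair.lesion_boxes],
        "volumes": {},
        "masks": {},
    }
    for tag, vol in (("high", pair.high), ("low", pair.low)):
        p = directory / f"{pair.patient_id}_{tag}{ext}"
        writer(vol, p)
        entry["volumes"][tag] = p.name
    for name, mask in pair.organ_masks.items():
        p = directory / f"{pair.patient_id}_mask_{name}.raw"
        np.asarray(mask, dtype="<u1").tofile(p)
        Path(str(p) + ".json").write_text(json.dumps({"shape": list(mask.shape), "dtype": "<u1"}))
        entry["masks"][name] = p.name
    return entry


def load_scan_pair(directory: str | Path, entry: dict) -> ScanPair:
    directory = Path(directory)
    reader = read_volume_raw if entry["format"] == "raw" else read_volume_nifti
    high = reader(directory / entry["volumes"]["high"])
    low = reader(directory / entry["volumes"]["low"])
    masks = {}
    for name, fname in entry["masks"].items():
        meta = json.loads((directory / (fname + ".json")).read_text())
        masks[name] = np.fromfile(directory / fname, dtype="<u1").reshape(meta["shape"]).astype(bool)
    boxes = [LesionBox(label=b["label"], box=tuple(b["box"])) for b in entry["lesion_boxes"]]
    return ScanPair(high=high, low=low, organ_masks=masks, lesion_boxes=boxes, seed=int(entry["seed"]))


def write_manifest(entries: list[dict], path: str | Path, *, seed: int, config_fingerprint: str) -> Path:
    path = Path(path)
    payload = {
        "version": MANIFEST_VERSION,
        "seed": seed,
        "config_fingerprint": config_fingerprint,
        "scans": sorted(entries, key=lambda e: (e["exam_type"], e["patient_id"])),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def read_manifest(path: str | Path) -> dict:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ManifestError(f"corrupted manifest {path}: {exc}") from exc
    if payload.get("version") != MANIFEST_VERSION:
        raise ManifestError(f"manifest version {payload.get('version')} != {MANIFEST_VERSION}")
    return payload
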