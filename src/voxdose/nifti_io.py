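"""NIfTI-1 volume I/O with JSON sidecar manifests.

Volumes (activity maps, label masks, cumulated-activity and dose maps) are
stored as NIfTI-1 with an isotropic diagonal affine; per-series and
per-cohort JSON manifests carry the metadata NIfTI does not (scan times,
patient ids, plan names, provenance).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ValidationError
from .metrics import LesionMask
from .tac import ScanSeries

__all__ = [
    "save_volume",
    "load_volume",
    "save_series",
    "load_series",
    "save_mask",
    "load_mask",
    "save_cohort",
    "load_cohort",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def save_volume(values: np.ndarray, voxel_size_mm: float, path: str | Path,
                sidecar: dict | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(values), _affine(voxel_size_mm))
    nib.save(img, str(path))
    if sidecar is not None:
        Path(path).with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_volume(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-5):
        raise ValidationError(f"{path}: anisotropic voxels {zooms} unsupported")
    return np.asarray(img.dataobj), float(zooms[0])


def save_series(series: ScanSeries, out_dir: str | Path) -> Path:
    """One NIfTI per scan time plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for k, t in enumerate(series.times_h):
        name = f"{series.patient_id}_t{k:02d}.nii"
        save_volume(series.maps[k], series.voxel_size_mm, out / name)
        files.append({"time_h": float(t), "file": name})
    manifest = {
        "patient_id": series.patient_id,
        "voxel_size_mm": series.voxel_size_mm,
        "units": "MBq",
        "scans": files,
    }
    path = out / f"{series.patient_id}_series.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def load_series(manifest_path: str | Path) -> ScanSeries:
    manifest_path = Path(manifest_path)
    doc = json.loads(manifest_path.read_text())
    times, maps = [], []
    for scan in doc["scans"]:
        values, voxel = load_volume(manifest_path.parent / scan["file"])
        times.append(scan["time_h"])
        maps.append(values)
    return ScanSeries(
        doc["patient_id"], np.asarray(times), np.stack(maps), float(doc["voxel_size_mm"])
    )


def save_mask(mask: LesionMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.int16), _affine(mask.voxel_size_mm))
    nib.save(img, str(path))


def load_mask(path: str | Path, patient_id: str) -> LesionMask:
    img = nib.load(str(path))
    return LesionMask(
        patient_id,
        np.asarray(img.dataobj).astype(np.int32),
        float(img.header.get_zooms()[0]),
    )


def save_cohort(datasets, out_dir: str | Path) -> Path:
    """Write a synthetic cohort in the exact formats the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients = []
    for ds in datasets:
        save_series(ds.series, out)
        mask_file = f"{ds.patient_id}_mask.nii"
        save_mask(ds.mask, out / mask_file)
        patients.append(
            {
                "patient_id": ds.patient_id,
                "series_manifest": f"{ds.patient_id}_series.json",
                "mask_file": mask_file,
                "plan": ds.plan_name,
            }
        )
    manifest = {"patients": patients}
    path = out / "cohort_manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def load_cohort(cohort_dir: str | Path) -> list[tuple[str, ScanSeries, LesionMask, str]]:
    cohort_dir = Path(cohort_dir)
    doc = json.loads((cohort_dir / "cohort_manifest.json").read_text())
    out = []
    for p in doc["patients"]:
        series = load_series(cohort_dir / p["series_manifest"])
        mask = load_mask(cohort_dir / p["mask_file"], p["patient_id"])
        out.append((p["patient_id"], series, mask, p["plan"]))
    return out
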