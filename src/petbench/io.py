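"""NIfTI + JSON-sidecar persistence for paired studies.

Volumes are stored as ``.nii.gz`` with the voxel spacing on the affine
diagonal (axis order (slice, row, col) maps directly to the array axes);
acquisition metadata lives in a ``meta.json`` sidecar with keys
``weight_kg, total_dose_MBq, half_life_s, delay_s, time_per_bed_s``.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .types import AcquisitionMeta, PairedStudy, PETVolume


def _affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def save_volume(path, values: np.ndarray, spacing) -> None:
    img = nib.Nifti1Image(np.asarray(values), _affine(spacing))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def save_study(study: PairedStudy, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t, vol in study.volumes.items():
        save_volume(out / f"pet_{t}s.nii.gz",
                    vol.values.astype(np.float32), vol.spacing)
    save_volume(out / "lesion_labels.nii.gz",
                study.lesion_labels.astype(np.int16), study.spacing)
    save_volume(out / "organ_labels.nii.gz",
                study.organ_labels.astype(np.int16), study.spacing)
    with open(out / "meta.json", "w") as fh:
        json.dump(study.meta.to_dict(), fh, indent=2)


def load_study(path) -> PairedStudy:
    p = Path(path)
    with open(p / "meta.json") as fh:
        meta = AcquisitionMeta.from_dict(json.load(fh))
    volumes: dict[int, PETVolume] = {}
    spacing = None
    for f in sorted(p.glob("pet_*s.nii.gz")):
        t = int(f.name[len("pet_"):-len("s.nii.gz")])
        values, spacing = load_volume(f)
        volumes[t] = PETVolume(values=np.asarray(values, dtype=np.float64),
                               spacing=spacing, meta=meta.with_time(t))
    lesions, _ = load_volume(p / "lesion_labels.nii.gz")
    organs, _ = load_volume(p / "organ_labels.nii.gz")
    return PairedStudy(
        volumes=volumes,
        lesion_labels=np.asarray(lesions, dtype=np.int32),
        organ_labels=np.asarray(organs, dtype=np.int32),
        meta=meta,
        spacing=spacing,
        patient_id=p.name,
    )


def load_split(dataset_dir, split: str) -> list[PairedStudy]:
    root = Path(dataset_dir)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    return [load_study(root / pid) for pid in manifest["splits"][split]]
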