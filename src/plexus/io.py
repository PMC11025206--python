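"""File formats: NIfTI-1 volumes, cohort CSV, and JSON artefacts.

Volumes round-trip bit-exactly for float64 images and integer label maps;
both plain ``.nii`` and gzipped ``.nii.gz`` are accepted. Masks are written
as uint8 NIfTI. Cohort tables use a fixed, documented CSV schema (see
:func:`plexus.cohort.generate_cohort`).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError
from .image import LabelMap, VENTRICULAR_SYSTEM_CODES, VolumeImage

COHORT_COLUMNS = [
    "subject_id", "group", "age", "sex", "education_years", "hars", "hdrs",
    "tiv_mm3", "cp_volume_mm3", "duration_months", "onset_site", "alsfrs_r",
    "bpr", "csf_albumin_mg_l", "serum_albumin_g_l", "qalb_mg_g",
]


def _load_nifti(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {img.shape}")
    if img.affine is None:
        raise FormatError(f"{path}: missing affine")
    return img


def read_volume(path) -> VolumeImage:
    """Read a 3-D NIfTI-1 intensity volume."""
    img = _load_nifti(path)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(
        np.asarray(img.dataobj, dtype=np.float64),
        voxel_size=zooms,
        affine=np.asarray(img.affine),
    )


def write_volume(image: VolumeImage, path) -> None:
    nifti = nib.Nifti1Image(image.intensities, image.affine)
    nifti.header.set_zooms(image.voxel_size)
    nib.save(nifti, str(path))


def read_labels(path, code_table: dict | None = None) -> LabelMap:
    """Read an aseg-style integer label volume."""
    img = _load_nifti(path)
    data = np.asarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise FormatError(f"{path}: label volume has non-integer values")
    return LabelMap(
        data.astype(np.int32),
        code_table=code_table or dict(VENTRICULAR_SYSTEM_CODES),
    )


def write_labels(labels: LabelMap, path, affine=None, voxel_size=(1, 1, 1)) -> None:
    aff = np.eye(4) if affine is None else np.asarray(affine)
    nifti = nib.Nifti1Image(labels.labels.astype(np.int16), aff)
    nifti.header.set_zooms(tuple(float(v) for v in voxel_size))
    nib.save(nifti, str(path))


def write_mask(mask: np.ndarray, path, affine=None, voxel_size=(1, 1, 1)) -> None:
    aff = np.eye(4) if affine is None else np.asarray(affine)
    nifti = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), aff)
    nifti.header.set_zooms(tuple(float(v) for v in voxel_size))
    nib.save(nifti, str(path))


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cohort CSV is missing columns {missing}")
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
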