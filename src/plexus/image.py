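"""In-memory containers for structural volumes and anatomical label maps.

A :class:`VolumeImage` is a 3-D scalar intensity grid with physical voxel
spacing (mm) and a 4x4 voxel-to-world affine (RAS convention, as stored in
NIfTI-1). A :class:`LabelMap` is an integer grid of anatomical codes over
the same grid, following the FreeSurfer ``aseg`` convention for the
ventricular system so that real FreeSurfer output is drop-in compatible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

# FreeSurfer aseg codes for the six ventricular-system structures that seed
# the initial choroid-plexus mask.
LEFT_LATERAL_VENTRICLE = 4
LEFT_INF_LATERAL_VENTRICLE = 5
LEFT_CHOROID_PLEXUS = 31
RIGHT_LATERAL_VENTRICLE = 43
RIGHT_INF_LATERAL_VENTRICLE = 44
RIGHT_CHOROID_PLEXUS = 63

VENTRICULAR_SYSTEM_CODES: dict[int, str] = {
    LEFT_LATERAL_VENTRICLE: "Left-Lateral-Ventricle",
    LEFT_INF_LATERAL_VENTRICLE: "Left-Inf-Lat-Vent",
    LEFT_CHOROID_PLEXUS: "Left-choroid-plexus",
    RIGHT_LATERAL_VENTRICLE: "Right-Lateral-Ventricle",
    RIGHT_INF_LATERAL_VENTRICLE: "Right-Inf-Lat-Vent",
    RIGHT_CHOROID_PLEXUS: "Right-choroid-plexus",
}


def _default_affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


@dataclass
class VolumeImage:
    """3-D intensity grid with voxel spacing in mm and a RAS affine."""

    intensities: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ParameterError(
                f"intensities must be 3-D, got ndim={self.intensities.ndim}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ParameterError("intensities must be finite")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ParameterError(
                f"voxel_size must be three positive floats, got {self.voxel_size}"
            )
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ParameterError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class LabelMap:
    """Integer anatomical label grid plus a code table (code -> name)."""

    labels: np.ndarray
    code_table: dict[int, str] = field(
        default_factory=lambda: dict(VENTRICULAR_SYSTEM_CODES)
    )

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ParameterError(f"labels must be 3-D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ParameterError("labels must be an integer grid")
        self.code_table = {int(k): str(v) for k, v in self.code_table.items()}

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask_for(self, codes) -> np.ndarray:
        """Boolean union of the voxels carrying any of ``codes``."""
        return np.isin(self.labels, np.asarray(list(codes)))


def check_aligned(image: VolumeImage, labels: LabelMap) -> None:
    """Raise unless the image and label grids share a shape."""
    if image.shape != labels.shape:
        raise ParameterError(
            f"image shape {image.shape} does not match label shape {labels.shape}"
        )
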