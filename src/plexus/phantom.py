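"""Synthetic brain phantoms with known choroid-plexus ground truth.

A phantom emulates the T1-weighted intensity structure of the ventricular
system that the segmentation pipeline relies on: dark CSF inside two
ellipsoidal lateral ventricles (plus small inferior-horn ellipsoids), an
intermediate-intensity partial-volume wall rim around each ventricle,
bright CP blobs floating in the ventricular CSF, and brighter background
parenchyma outside. A light Gaussian blur emulates partial-volume mixing at
tissue interfaces, and additive Gaussian noise emulates scanner noise.

The label map follows the FreeSurfer aseg codes (4/43 lateral ventricle,
5/44 inferior lateral ventricle, 31/63 choroid plexus) and covers exactly
the ventricle interior + wall rim + CP blobs, so ``build_initial_mask``
recovers the full phantom ventricular system. The returned ground-truth
mask is the exact voxelised union of the CP blobs (voxel centres inside a
blob sphere); noise is the only stochastic element of the image given the
blob geometry, which is itself drawn reproducibly from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ParameterError
from .image import (
    LEFT_CHOROID_PLEXUS,
    LEFT_INF_LATERAL_VENTRICLE,
    LEFT_LATERAL_VENTRICLE,
    RIGHT_CHOROID_PLEXUS,
    RIGHT_INF_LATERAL_VENTRICLE,
    RIGHT_LATERAL_VENTRICLE,
    VENTRICULAR_SYSTEM_CODES,
    LabelMap,
    VolumeImage,
)


@dataclass
class PhantomSpec:
    """Phantom geometry, intensities, and noise.

    Units are mm for geometry and arbitrary T1-like units for intensities.
    The intensity ordering csf < wall < cp is required (and validated): the
    stage-2 "highest mean intensity" selection rule presumes bright CP.
    ``pv_blur_sigma_mm`` controls the partial-volume emulation applied to
    the noiseless piecewise-constant image before noise is added.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: float = 1.0
    ventricle_semiaxes: tuple[float, float, float] = (9.0, 21.0, 11.0)
    inf_ventricle_semiaxes: tuple[float, float, float] = (3.5, 8.0, 3.5)
    wall_thickness: float = 2.0
    cp_blob_count: int = 3
    cp_blob_radius_mm: float = 3.0
    blob_radius_jitter: float = 0.15  # relative SD of per-blob radius
    intensity_means: dict = field(
        default_factory=lambda: {"background": 100.0, "csf": 30.0,
                                 "wall": 70.0, "cp": 110.0}
    )
    pv_blur_sigma_mm: float = 0.3
    noise_sd: float = 5.0
    seed: int = 0
    geometry_seed: int = 1234  # blob layout; independent of the noise seed

    def __post_init__(self):
        im = self.intensity_means
        if not (im["csf"] < im["wall"] < im["cp"]):
            raise ParameterError(
                "intensity ordering csf < wall < cp is required, got "
                f"csf={im['csf']}, wall={im['wall']}, cp={im['cp']}"
            )
        for name in ("voxel_size", "wall_thickness", "cp_blob_radius_mm"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if any(a <= 0 for a in self.ventricle_semiaxes + self.inf_ventricle_semiaxes):
            raise ParameterError("semiaxes must be positive")
        if self.cp_blob_count < 1:
            raise ParameterError("cp_blob_count must be >= 1")
        if self.noise_sd < 0 or self.pv_blur_sigma_mm < 0:
            raise ParameterError("noise_sd and pv_blur_sigma_mm must be >= 0")


def _ellipsoid_rho2(coords_mm, centre, semiaxes):
    """Squared normalised ellipsoid coordinate; <= 1 is interior."""
    r2 = 0.0
    for c, c0, a in zip(coords_mm, centre, semiaxes):
        r2 = r2 + ((c - c0) / a) ** 2
    return r2


def _place_blobs(rng, centre, semiaxes, spec):
    """Draw non-overlapping blob centres and radii fully inside the
    ellipsoid interior (margin: one voxel inside the CSF region)."""
    placed = []  # (centre_mm, radius)
    margin = spec.voxel_size
    for _ in range(spec.cp_blob_count):
        ok = False
        for _try in range(2000):
            radius = spec.cp_blob_radius_mm * float(
                1.0 + spec.blob_radius_jitter * rng.standard_normal()
            )
            radius = max(radius, 0.4 * spec.cp_blob_radius_mm)
            # uniform in the bounding box, accept if the whole sphere fits
            u = rng.uniform(-1.0, 1.0, size=3)
            cand = np.array(centre) + u * np.array(semiaxes)
            shrink = [a - radius - margin for a in semiaxes]
            if any(s <= 0 for s in shrink):
                break
            if _ellipsoid_rho2(cand, centre, shrink) > 1.0:
                continue
            if any(
                np.linalg.norm(cand - c0) < (radius + r0) for c0, r0 in placed
            ):
                continue
            placed.append((cand, radius))
            ok = True
            break
        if not ok:
            raise GeometryError(
                f"could not place a CP blob of radius ~{spec.cp_blob_radius_mm} mm "
                f"inside ventricle semiaxes {semiaxes} after 2000 attempts"
            )
    return placed


def generate_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[VolumeImage, LabelMap, np.ndarray]:
    """Build (intensity volume, label map, CP ground-truth mask).

    Identical specs (including seeds) give bit-identical outputs. Blob
    layout is drawn from ``geometry_seed`` only, so phantoms differing only
    in ``seed`` share masks and ground truth exactly and differ only in the
    noise field.
    """
    spec = spec or PhantomSpec()
    geom_rng = np.random.default_rng(spec.geometry_seed)
    noise_rng = np.random.default_rng(spec.seed)

    nx, ny, nz = spec.grid_shape
    vs = spec.voxel_size
    grid = np.meshgrid(
        np.arange(nx) * vs, np.arange(ny) * vs, np.arange(nz) * vs, indexing="ij"
    )
    centre_mm = np.array([(n - 1) * vs / 2.0 for n in spec.grid_shape])

    im = spec.intensity_means
    intensities = np.full(spec.grid_shape, im["background"], dtype=np.float64)
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    truth = np.zeros(spec.grid_shape, dtype=bool)

    sides = (
        (-1.0, LEFT_LATERAL_VENTRICLE, LEFT_INF_LATERAL_VENTRICLE,
         LEFT_CHOROID_PLEXUS),
        (+1.0, RIGHT_LATERAL_VENTRICLE, RIGHT_INF_LATERAL_VENTRICLE,
         RIGHT_CHOROID_PLEXUS),
    )
    lat_offset = np.array([0.30 * (nx - 1) * vs / 2.0, 0.0, 0.04 * (nz - 1) * vs])
    inf_offset = np.array([0.48 * (nx - 1) * vs / 2.0, 0.12 * (ny - 1) * vs,
                           -0.30 * (nz - 1) * vs / 2.0])

    for sign, lat_code, inf_code, cp_code in sides:
        for centre, semiaxes, code in (
            (centre_mm + np.array([sign, 1.0, 1.0]) * lat_offset,
             spec.ventricle_semiaxes, lat_code),
            (centre_mm + np.array([sign, 1.0, 1.0]) * inf_offset,
             spec.inf_ventricle_semiaxes, inf_code),
        ):
            outer_axes = tuple(a + spec.wall_thickness for a in semiaxes)
            inner = _ellipsoid_rho2(grid, centre, semiaxes) <= 1.0
            outer = _ellipsoid_rho2(grid, centre, outer_axes) <= 1.0
            rim = outer & ~inner
            intensities[rim & (labels == 0)] = im["wall"]
            intensities[inner] = im["csf"]
            labels[outer & (labels == 0)] = code

        # CP blobs live in the lateral-ventricle CSF
        lat_centre = centre_mm + np.array([sign, 1.0, 1.0]) * lat_offset
        for blob_centre, radius in _place_blobs(
            geom_rng, lat_centre, spec.ventricle_semiaxes, spec
        ):
            d2 = sum((g - c) ** 2 for g, c in zip(grid, blob_centre))
            blob = d2 <= radius * radius
            truth |= blob
            intensities[blob] = im["cp"]
            labels[blob] = cp_code

    if spec.pv_blur_sigma_mm > 0:
        intensities = ndimage.gaussian_filter(
            intensities, sigma=spec.pv_blur_sigma_mm / vs, mode="nearest"
        )
    if spec.noise_sd > 0:
        intensities = intensities + noise_rng.normal(
            0.0, spec.noise_sd, size=spec.grid_shape
        )

    image = VolumeImage(intensities, voxel_size=(vs, vs, vs))
    label_map = LabelMap(labels, code_table=dict(VENTRICULAR_SYSTEM_CODES))
    return image, label_map, truth


def true_volume_mm3(truth: np.ndarray, voxel_size: float | tuple) -> float:
    """Ground-truth CP volume in mm^3."""
    vs = (voxel_size,) * 3 if np.isscalar(voxel_size) else tuple(voxel_size)
    return float(truth.sum()) * float(np.prod(vs))
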