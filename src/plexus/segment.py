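"""Choroid-plexus segmentation from a structural volume and an aseg-style
label map.

The pipeline mirrors the standard GMM-based CP volumetry procedure:

1. ``build_initial_mask`` — union of the six ventricular-system labels
   (left/right lateral ventricle, inferior lateral ventricle, choroid
   plexus).
2. ``stage1_cluster`` — 2-component mixture on the initial-mask intensities;
   the higher-mean class is the CP + ventricle-wall class, the lower-mean
   class is CSF.
3. ``susan_smooth`` — edge-preserving smoothing (sigma = 1 mm by default)
   restricted to the high-intensity class.
4. ``stage2_cluster`` — 3-component mixture on the smoothed values; voxels
   hard-assigned to the highest-mean component form the CP mask.
5. ``apply_manual_edits`` — optional reproducible surrogate for expert
   manual correction, as explicit add/remove voxel lists.
6. ``compute_volume`` — voxel count times voxel volume, in mm^3.

``segment_cp`` composes the stages and records full provenance. Masks are
nested by construction: final CP mask <= stage-1 high mask <= initial mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import FitError, MaskError, ParameterError, SegmentationError
from .gmm import GMMConfig, GMMFit, fit_gmm, select_component
from .image import LabelMap, VENTRICULAR_SYSTEM_CODES, VolumeImage, check_aligned
from .susan import susan_smooth

MIN_STAGE2_VOXELS = 30


@dataclass
class SegmentationConfig:
    """Pipeline parameters; defaults follow the standard procedure."""

    sigma_mm: float = 1.0
    brightness_threshold: float | None = None  # None -> 0.1 * (P95 - P5) rule
    radius_factor: float = 3.0
    gmm: GMMConfig = field(default_factory=GMMConfig)
    min_component_voxels: int | None = None  # optional size filter, off by default


@dataclass
class ManualEdits:
    """Reproducible surrogate for expert correction of the CP mask.

    ``remove`` is applied before ``add``; a voxel listed in both ends up in
    the mask. Indices are (i, j, k) voxel triples, 0-based.
    """

    add: Sequence[tuple[int, int, int]] = ()
    remove: Sequence[tuple[int, int, int]] = ()


@dataclass
class SegmentationResult:
    initial_mask: np.ndarray
    stage1_low_mask: np.ndarray
    stage1_high_mask: np.ndarray
    smoothed: np.ndarray
    final_cp_mask: np.ndarray
    cp_volume_mm3: float
    stage1_fit: GMMFit
    stage2_fit: GMMFit
    provenance: dict


def build_initial_mask(labels: LabelMap) -> tuple[np.ndarray, int]:
    """Union of the six ventricular-system structures; returns (mask, count).

    Requires all six codes in the code table (their voxel counts may be
    zero) and raises :class:`MaskError` if the union is empty.
    """
    missing = [c for c in VENTRICULAR_SYSTEM_CODES if c not in labels.code_table]
    if missing:
        raise MaskError(
            f"label code table is missing ventricular-system codes {missing}"
        )
    mask = labels.mask_for(VENTRICULAR_SYSTEM_CODES)
    count = int(mask.sum())
    if count == 0:
        raise MaskError("initial mask is empty; pipeline cannot proceed")
    return mask, count


def stage1_cluster(
    image: VolumeImage, mask: np.ndarray, config: GMMConfig | None = None
) -> tuple[np.ndarray, np.ndarray, GMMFit]:
    """Split the initial mask into a low-mean (CSF) and a high-mean
    (CP + ventricle wall) class by a 2-component mixture fit."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MaskError("stage-1 mask is empty")
    fit = fit_gmm(image.intensities[mask], k=2, config=config)
    assign = fit.hard_assignment()
    hi = select_component(fit.means, fit.variances, "highest")
    high_mask = np.zeros(image.shape, dtype=bool)
    low_mask = np.zeros(image.shape, dtype=bool)
    high_mask[mask] = assign == hi
    low_mask[mask] = assign != hi
    return low_mask, high_mask, fit


def stage2_cluster(
    smoothed: np.ndarray, domain_mask: np.ndarray, config: GMMConfig | None = None
) -> tuple[np.ndarray, GMMFit]:
    """3-component mixture on the smoothed values; the highest-mean
    component's voxels form the final CP mask."""
    domain_mask = np.asarray(domain_mask, dtype=bool)
    n = int(domain_mask.sum())
    if n == 0:
        raise MaskError("stage-2 domain mask is empty")
    if n < MIN_STAGE2_VOXELS:
        raise MaskError(
            f"stage-2 domain mask has {n} voxels; need >= {MIN_STAGE2_VOXELS}"
        )
    fit = fit_gmm(smoothed[domain_mask], k=3, config=config)
    assign = fit.hard_assignment()
    cp = select_component(fit.means, fit.variances, "highest")
    final = np.zeros(domain_mask.shape, dtype=bool)
    final[domain_mask] = assign == cp
    return final, fit


def apply_manual_edits(mask: np.ndarray, edits: ManualEdits) -> np.ndarray:
    """Apply an edit list: removals first, then additions.

    Repeated application of the same edit list is idempotent. Out-of-grid
    indices raise :class:`MaskError`.
    """
    out = np.asarray(mask, dtype=bool).copy()
    shape = out.shape
    for name, idx_list in (("remove", edits.remove), ("add", edits.add)):
        for idx in idx_list:
            idx = tuple(int(i) for i in idx)
            if len(idx) != 3 or any(
                i < 0 or i >= s for i, s in zip(idx, shape)
            ):
                raise MaskError(f"{name} index {idx} outside grid {shape}")
    for idx in edits.remove:
        out[tuple(int(i) for i in idx)] = False
    for idx in edits.add:
        out[tuple(int(i) for i in idx)] = True
    return out


def compute_volume(mask: np.ndarray, voxel_size) -> float:
    """Volume of a boolean mask in mm^3: voxel count x voxel volume."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        raise ParameterError("mask must be boolean")
    return float(mask.sum()) * float(np.prod(voxel_size))


def _size_filter(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    from scipy import ndimage

    lab, n = ndimage.label(mask)
    if n == 0:
        return mask
    counts = np.bincount(lab.ravel())
    keep = np.zeros_like(counts, dtype=bool)
    keep[1:] = counts[1:] >= min_voxels
    return keep[lab]


def segment_cp(
    image: VolumeImage,
    labels: LabelMap,
    config: SegmentationConfig | None = None,
    edits: ManualEdits | None = None,
) -> SegmentationResult:
    """Run the full CP segmentation pipeline; the first failing stage aborts
    with a stage-tagged :class:`SegmentationError`."""
    config = config or SegmentationConfig()
    check_aligned(image, labels)

    def run(stage, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except (FitError, MaskError, ParameterError) as e:
            raise SegmentationError(stage, str(e)) from e

    initial_mask, n_initial = run("initial_mask", build_initial_mask, labels)
    low_mask, high_mask, fit1 = run(
        "stage1_cluster", stage1_cluster, image, initial_mask, config.gmm
    )
    smoothed = run(
        "susan_smooth",
        susan_smooth,
        image,
        high_mask,
        config.sigma_mm,
        config.brightness_threshold,
        config.radius_factor,
    )
    final, fit2 = run("stage2_cluster", stage2_cluster, smoothed, high_mask,
                      config.gmm)
    if config.min_component_voxels:
        final = _size_filter(final, config.min_component_voxels)
    if edits is not None:
        final = run("manual_edits", apply_manual_edits, final, edits)
        final &= high_mask  # edits cannot break the nesting invariant
    volume = compute_volume(final, image.voxel_size)

    provenance = {
        "config": {
            "sigma_mm": config.sigma_mm,
            "brightness_threshold": config.brightness_threshold,
            "radius_factor": config.radius_factor,
            "gmm_mode": config.gmm.mode,
            "gmm_init": config.gmm.init,
            "gmm_tol": config.gmm.tol,
            "gmm_max_iter": config.gmm.max_iter,
            "gmm_seed": config.gmm.seed,
            "min_component_voxels": config.min_component_voxels,
        },
        "voxel_counts": {
            "initial": n_initial,
            "stage1_high": int(high_mask.sum()),
            "stage1_low": int(low_mask.sum()),
            "final_cp": int(final.sum()),
        },
        "stage1_means": fit1.means.tolist(),
        "stage2_means": fit2.means.tolist(),
        "edits_applied": edits is not None,
    }
    return SegmentationResult(
        initial_mask=initial_mask,
        stage1_low_mask=low_mask,
        stage1_high_mask=high_mask,
        smoothed=smoothed,
        final_cp_mask=final,
        cp_volume_mm3=volume,
        stage1_fit=fit1,
        stage2_fit=fit2,
        provenance=provenance,
    )
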