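"""Semi-automatic bone extraction from CT and urinary-activity suppression.

Bone is extracted by thresholding on Hounsfield units at a level chosen from
the cortical bone density, followed by morphological closing and removal of
small components; internal cavities (marrow enclosed by the cortical shell)
are re-filled with a close-holes step.  High bone-seeking-tracer activity in
the urinary tract and bladder is suppressed by removing bright SPECT
components that lie entirely outside the (dilated) bone mask.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, GeometryError, Volume

#: 26-connectivity for foreground components, 6-connectivity for background
#: holes — the standard complementary pairing that avoids topological
#: paradoxes on the digital grid.
_CONN26 = np.ones((3, 3, 3), dtype=bool)
_CONN6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class SegmentationParams:
    """Tunable parameters of the bone/urinary segmentation stage.

    bone_threshold : HU level; voxels >= threshold are bone candidates.
        150 HU suits diagnostic CT; 100 HU the noisier low-dose setting.
    min_component_volume : mm^3 below which a connected component is dropped.
    closing_radius : radius in mm of the ball structuring element used for
        morphological closing of the thresholded mask.
    urinary_percentile : fraction of the SPECT maximum above which a voxel
        counts as "hot" when searching for urinary components.
    urinary_margin : mm of dilation applied to the bone mask; hot components
        intersecting the dilated mask are protected.
    """

    bone_threshold: float = 150.0
    min_component_volume: float = 100.0
    closing_radius: float = 2.0
    urinary_percentile: float = 0.6
    urinary_margin: float = 10.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.bone_threshold):
            raise ValueError("bone_threshold must be finite")
        if self.closing_radius < 0:
            raise ValueError("closing_radius must be >= 0")
        if not 0 < self.urinary_percentile <= 1:
            raise ValueError("urinary_percentile must be in (0, 1]")


def _ball(radius_vox: np.ndarray) -> np.ndarray:
    """Discrete ellipsoidal ball with per-axis radius in voxels."""
    r = np.maximum(np.asarray(radius_vox, dtype=float), 0.0)
    half = np.ceil(r).astype(int)
    grids = np.ogrid[tuple(slice(-h, h + 1) for h in half)]
    dist = sum((g / max(ri, 1e-9)) ** 2 for g, ri in zip(grids, r)) if r.max() > 0 else None
    if dist is None:
        return np.ones((1, 1, 1), dtype=bool)
    return dist <= 1.0 + 1e-9


def extract_bone(ct: Volume, params: SegmentationParams | None = None) -> BinaryMask:
    """Threshold CT at ``bone_threshold`` HU, close, drop small components.

    The >= convention includes a voxel exactly at the threshold.  The result
    is deterministic; an empty mask only warns (valid for air-only input).
    """
    params = params or SegmentationParams()
    mask = ct.values >= params.bone_threshold
    if params.closing_radius > 0:
        se = _ball(params.closing_radius / ct.spacing)
        mask = ndimage.binary_closing(mask, structure=se)
    if params.min_component_volume > 0 and mask.any():
        labels, n = ndimage.label(mask, structure=_CONN26)
        if n > 0:
            counts = np.bincount(labels.ravel())
            min_vox = params.min_component_volume / ct.voxel_volume
            keep = counts >= min_vox
            keep[0] = False
            mask = keep[labels]
    if not mask.any():
        warnings.warn("bone extraction produced an empty mask")
    return BinaryMask(values=mask, affine=ct.affine.copy())


def close_holes(mask: BinaryMask) -> BinaryMask:
    """Fill internal cavities: background not reachable from the border.

    Every background component (6-connectivity) that cannot be reached from
    the volume border becomes foreground; foreground is never removed, so the
    operation is extensive and idempotent.
    """
    filled = ndimage.binary_fill_holes(mask.values, structure=_CONN6)
    return mask.copy_with(filled)


def remove_urinary_activity(spect: Volume, bone: BinaryMask,
                            params: SegmentationParams | None = None) -> Volume:
    """Zero hot SPECT components that lie entirely outside the dilated bone.

    Emulates the automatic elimination of urinary tract and bladder activity:
    connected components of ``spect >= urinary_percentile * max`` whose voxels
    all fall outside the bone mask dilated by ``urinary_margin`` mm are set to
    zero.  Voxels inside the dilated mask — skeletal uptake — are never
    altered.  ``spect`` must already live on the bone grid.
    """
    params = params or SegmentationParams()
    if spect.shape != bone.shape:
        raise GeometryError(
            f"SPECT grid {spect.shape} does not match bone grid {bone.shape}; "
            "resample first")
    out = spect.values.copy()
    peak = out.max()
    if peak <= 0:
        return spect.copy_with(out)
    hot = out >= params.urinary_percentile * peak
    if not hot.any():
        return spect.copy_with(out)
    if bone.values.any() and params.urinary_margin > 0:
        dist = ndimage.distance_transform_edt(~bone.values, sampling=spect.spacing)
        protected = dist <= params.urinary_margin
    else:
        protected = bone.values
    labels, n = ndimage.label(hot, structure=_CONN26)
    for lab in range(1, n + 1):
        comp = labels == lab
        if not protected[comp].any():
            out[comp] = 0.0
    return spect.copy_with(out)


def suggest_threshold(ct: Volume, cortex_probe_points, fraction: float = 0.5) -> float:
    """Advisory HU threshold: ``fraction`` of the median HU at probe points.

    ``cortex_probe_points`` are world-mm points the operator placed on the
    bone cortex; half the cortical density separates cortex from marrow and
    soft tissue in typical CT.
    """
    pts = np.atleast_2d(np.asarray(cortex_probe_points, dtype=np.float64))
    if pts.size == 0:
        raise GeometryError("at least one probe point is required")
    idx = np.atleast_2d(ct.world_to_voxel(pts))
    nearest = np.round(idx).astype(int)
    shape = np.array(ct.shape)
    if np.any(nearest < 0) or np.any(nearest >= shape):
        raise GeometryError(f"probe point(s) outside the volume: {nearest.tolist()}")
    values = ct.values[nearest[:, 0], nearest[:, 1], nearest[:, 2]]
    return float(fraction * np.median(values))
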