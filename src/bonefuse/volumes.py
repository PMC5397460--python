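"""Volume data model, file I/O, coordinate transforms and resampling.

All geometry is handled in world millimetres.  A :class:`Volume` couples a
scalar voxel array (Hounsfield units for CT, counts for SPECT) with a 4x4
voxel-index -> world affine, following the NIfTI convention of 0-based,
cell-centered voxel indices.  SPECT and CT live on different grids (SPECT
voxels are 4-10 mm, CT 1-2 mm); :func:`resample_to_grid` makes the mismatch
explicit by trilinear interpolation through an optional rigid transform.
"""
from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


class GeometryError(ValueError):
    """Inconsistent or degenerate spatial metadata (affines, grids, spacing)."""


class FormatError(ValueError):
    """A file that does not parse as the named standard."""


@dataclass
class Volume:
    """Scalar field on a regular 3D grid with a voxel->world affine.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel scalars; HU for CT, counts for SPECT.
    affine : ndarray, shape (4, 4)
        Maps 0-based voxel index (cell center) to world mm.
    modality : {"ct", "spect"}
    """

    values: np.ndarray
    affine: np.ndarray
    modality: str = "ct"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise GeometryError(f"volume shape must be 3D positive, got {self.values.shape}")
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine is not invertible")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, idx) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=np.float64))
        pts = idx @ self.affine[:3, :3].T + self.affine[:3, 3]
        return np.squeeze(pts)

    def world_to_voxel(self, point_mm) -> np.ndarray:
        """Continuous voxel index of a world point; exact inverse of voxel_to_world."""
        pts = np.atleast_2d(np.asarray(point_mm, dtype=np.float64))
        inv = np.linalg.inv(self.affine)
        idx = pts @ inv[:3, :3].T + inv[:3, 3]
        return np.squeeze(idx)

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned world bounding box of the voxel cells (± half voxel)."""
        n = np.array(self.shape, dtype=np.float64)
        corners = np.array([[i, j, k] for i in (-0.5, n[0] - 0.5)
                            for j in (-0.5, n[1] - 0.5)
                            for k in (-0.5, n[2] - 0.5)])
        w = np.atleast_2d(self.voxel_to_world(corners))
        return w.min(axis=0), w.max(axis=0)

    def copy_with(self, values: np.ndarray) -> "Volume":
        return Volume(values=np.asarray(values, dtype=np.float64),
                      affine=self.affine.copy(), modality=self.modality)


@dataclass
class BinaryMask:
    """Boolean field aligned to a companion :class:`Volume` grid."""

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.values.ndim != 3:
            raise GeometryError("mask must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def same_grid(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=1e-6)

    def copy_with(self, values: np.ndarray) -> "BinaryMask":
        return BinaryMask(values=np.asarray(values, dtype=bool), affine=self.affine.copy())


@dataclass
class RigidTransform:
    """Rigid world->world map x' = R x + t (mm); defaults to identity.

    Registration is never estimated here: on hybrid SPECT/CT scanners the two
    acquisitions share a patient position, so misalignment is expected to be
    minimal and identity is the default.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise GeometryError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise GeometryError("rotation determinant must be +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return np.squeeze(pts @ self.rotation.T + self.translation)


def make_grid(shape, spacing, origin=(0.0, 0.0, 0.0), modality: str = "ct") -> Volume:
    """Zero-filled Volume on an axis-aligned grid (a 'grid spec')."""
    shape = tuple(int(s) for s in shape)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=np.float64), (3,))
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = np.asarray(origin, dtype=np.float64)
    return Volume(values=np.zeros(shape), affine=affine, modality=modality)


def read_volume(path: str, format: str | None = None, modality: str = "ct") -> Volume:
    """Read a NIfTI file or a DICOM series directory into a Volume.

    The affine comes from the header (NIfTI sform/qform; DICOM patient
    orientation/position + pixel and slice spacing).  DICOM rescale
    slope/intercept is applied so CT values are in HU.
    """
    if format is None:
        format = "dicom_series" if os.path.isdir(path) else "nifti"
    if format == "nifti":
        try:
            img = nib.load(path)
        except Exception as exc:  # nibabel raises several types
            raise FormatError(f"cannot read NIfTI file {path!r}: {exc}") from exc
        data = np.asarray(img.get_fdata(), dtype=np.float64)
        if data.ndim != 3:
            raise FormatError(f"expected a 3D NIfTI volume, got shape {data.shape}")
        return Volume(values=data, affine=np.asarray(img.affine), modality=modality)
    if format == "dicom_series":
        return _read_dicom_series(path, modality=modality)
    raise FormatError(f"unknown format {format!r}")


def _read_dicom_series(directory: str, modality: str = "ct") -> Volume:
    import pydicom

    files = sorted(
        os.path.join(directory, f) for f in os.listdir(directory)
        if not f.startswith(".")
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception as exc:
            raise FormatError(f"cannot parse DICOM file {f!r}: {exc}") from exc
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no DICOM image slices found in {directory!r}")

    first = slices[0]
    row_dir = np.array(first.ImageOrientationPatient[:3], dtype=np.float64)
    col_dir = np.array(first.ImageOrientationPatient[3:], dtype=np.float64)
    normal = np.cross(row_dir, col_dir)
    slices.sort(key=lambda s: float(np.dot(np.array(s.ImagePositionPatient, float), normal)))

    positions = np.array([np.dot(np.array(s.ImagePositionPatient, float), normal)
                          for s in slices])
    if len(slices) > 1:
        gaps = np.diff(positions)
        if np.ptp(gaps) > 1e-3 * max(1.0, abs(gaps[0])):
            raise GeometryError(f"inconsistent DICOM slice spacing: gaps {gaps}")
        slice_spacing = float(gaps[0])
    else:
        slice_spacing = float(getattr(first, "SliceThickness", 1.0))

    row_spacing, col_spacing = (float(v) for v in first.PixelSpacing)
    stack = []
    for s in slices:
        arr = s.pixel_array.astype(np.float64)
        slope = float(getattr(s, "RescaleSlope", 1.0))
        intercept = float(getattr(s, "RescaleIntercept", 0.0))
        stack.append(arr * slope + intercept)
    # pixel_array is (rows, cols): index (i=col, j=row, k=slice)
    values = np.transpose(np.stack(stack, axis=-1), (1, 0, 2))

    affine = np.eye(4)
    affine[:3, 0] = row_dir * col_spacing      # step between columns
    affine[:3, 1] = col_dir * row_spacing      # step between rows
    affine[:3, 2] = normal * slice_spacing
    affine[:3, 3] = np.array(slices[0].ImagePositionPatient, dtype=np.float64)
    return Volume(values=values, affine=affine, modality=modality)


def write_volume(vol: Volume, path: str) -> None:
    """Write a Volume as NIfTI-1 (.nii or .nii.gz)."""
    nib.save(nib.Nifti1Image(vol.values, vol.affine), path)


def write_mask(mask: BinaryMask, path: str) -> None:
    nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), mask.affine), path)


def read_mask(path: str) -> BinaryMask:
    vol = read_volume(path, format="nifti")
    return BinaryMask(values=vol.values > 0.5, affine=vol.affine)


def resample_to_grid(src: Volume, target_grid: Volume,
                     transform: RigidTransform | None = None) -> Volume:
    """Resample ``src`` onto ``target_grid`` by trilinear interpolation.

    ``transform`` maps src world coordinates to target world coordinates
    (identity by default, the hybrid-scanner assumption); each target voxel
    center is mapped through its inverse into src index space.  Samples
    outside src are 0 (air / no counts).
    """
    if transform is None:
        transform = RigidTransform.identity()
    m = (np.linalg.inv(src.affine) @ transform.inverse().as_matrix()
         @ target_grid.affine)
    out = ndimage.affine_transform(
        src.values, matrix=m[:3, :3], offset=m[:3, 3],
        output_shape=target_grid.shape, order=1, mode="constant", cval=0.0,
        prefilter=False)
    lo, hi = src.world_bounds()
    tlo, thi = target_grid.world_bounds()
    if np.any(hi < tlo) or np.any(lo > thi):
        warnings.warn("source and target grids do not overlap in world space")
    return Volume(values=out, affine=target_grid.affine.copy(), modality=src.modality)
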