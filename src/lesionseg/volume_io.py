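"""NIfTI volume I/O, voxel geometry, and intensity normalization.

Volumes are carried as plain dataclasses wrapping a 3D numpy array
indexed ``(x, y, z)`` (NIfTI's first three dimensions), the per-axis
voxel spacing in millimetres, and the affine orientation matrix.  The
affine is opaque metadata: it is preserved on round trip but never used
to resample or reorient.

Intensity normalization is the per-volume standardization applied before
training and inference: subtract the mean and divide by the population
standard deviation so the volume has zero mean and unit variance.  It is
computed over *all* voxels — no brain masking or other preprocessing is
assumed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from lesionseg.errors import DegenerateImageError, GeometryError, InvalidConfigError

__all__ = [
    "VolumeImage",
    "SegmentationMask",
    "load_volume",
    "save_volume",
    "normalize",
]


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class VolumeImage:
    """A 3D scalar intensity grid with physical voxel geometry.

    Parameters
    ----------
    data
        3D float array, indexed (x, y, z).
    spacing
        Millimetres per voxel along each axis; strictly positive.
    affine
        4x4 voxel-to-world matrix.  Preserved, never interpreted.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise InvalidConfigError(f"expected 3D data, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InvalidConfigError(f"spacing must be 3 positive reals, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise InvalidConfigError("image data contains non-finite values")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        else:
            self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "VolumeImage | SegmentationMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class SegmentationMask:
    """A binary 3D label grid sharing a :class:`VolumeImage`'s geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        values = np.unique(arr)
        if not np.isin(values, (0, 1)).all():
            raise InvalidConfigError(f"mask values must be 0/1, found {values[:10]}")
        self.data = arr.astype(np.uint8)
        if self.data.ndim != 3:
            raise InvalidConfigError(f"expected 3D mask, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InvalidConfigError(f"spacing must be 3 positive reals, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        else:
            self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "VolumeImage | SegmentationMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def bool(self) -> np.ndarray:
        return self.data.astype(bool)


def require_same_geometry(a, b) -> None:
    """Raise :class:`GeometryError` unless ``a`` and ``b`` share shape and spacing."""
    if a.data.shape != b.data.shape:
        raise GeometryError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise GeometryError(f"spacing mismatch: {a.spacing} vs {b.spacing}")


def load_volume(path: str | os.PathLike, *, as_mask: bool = False):
    """Load a 3D NIfTI-1 volume.

    Spacing is read from the header's per-axis pixel dimensions and the
    affine is carried through unchanged.

    Parameters
    ----------
    path
        Path to a ``.nii`` or ``.nii.gz`` file.
    as_mask
        Return a :class:`SegmentationMask` (values must be 0/1) instead
        of a :class:`VolumeImage`.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    InvalidConfigError
        If the image is not 3D or the header spacing is non-positive.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    shape = img.shape
    if len(shape) != 3:
        raise InvalidConfigError(f"expected a 3D image, file has shape {shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise InvalidConfigError(f"non-positive voxel spacing in header: {spacing}")
    data = np.asanyarray(img.dataobj)
    affine = img.affine
    if as_mask:
        return SegmentationMask(data=data, spacing=spacing, affine=affine)
    return VolumeImage(data=data.astype(np.float32), spacing=spacing, affine=affine)


def save_volume(v: VolumeImage | SegmentationMask, path: str | os.PathLike) -> str:
    """Write a volume or mask as NIfTI-1 and return the path.

    Images are stored as 32-bit float, masks as unsigned 8-bit.  The
    header zooms are set from ``v.spacing`` and the affine from
    ``v.affine`` so that :func:`load_volume` round-trips both.
    """
    path = os.fspath(path)
    if isinstance(v, SegmentationMask):
        data = v.data.astype(np.uint8)
    else:
        data = v.data.astype(np.float32)
    img = nib.Nifti1Image(data, v.affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, path)
    return path


def normalize(v: VolumeImage) -> VolumeImage:
    """Zero-center a volume and scale it to unit variance.

    The mean and the population variance (divide by N) are taken over
    all voxels.  Geometry is unchanged.  Idempotent up to floating
    tolerance.

    Raises
    ------
    DegenerateImageError
        If the volume has (numerically) zero variance.
    """
    if v.data.size <= 1:
        raise DegenerateImageError("cannot normalize a volume with a single voxel")
    data = v.data.astype(np.float64)
    mean = data.mean()
    std = data.std()  # population convention (ddof=0)
    if std == 0 or not np.isfinite(std):
        raise DegenerateImageError("constant image: variance is zero")
    out = ((data - mean) / std).astype(np.float32)
    return VolumeImage(data=out, spacing=v.spacing, affine=v.affine)
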