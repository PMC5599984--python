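"""Volumetric image data model, NIfTI-1 I/O and rigid label resampling.

Every spatial object in the pipeline is carried by :class:`VolumetricImage`
(a 3-D voxel array plus a 4x4 voxel-index -> world-mm affine, NIfTI
convention: index (0,0,0) maps through the affine directly, world
coordinates RAS+).  Segmentations are :class:`LabelMask` instances whose
voxels are non-negative integer labels; by convention label 1 is the left
hippocampus and label 2 the right hippocampus.

Rigid transforms are plain 4x4 world-mm -> world-mm matrices, read and
written as 4-line whitespace-separated text files (the dialect emitted by
common registration tools).  Only transform *application* is implemented;
estimating the registration is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumetricImage",
    "LabelMask",
    "RigidTransform",
    "GridMismatchError",
    "FormatError",
    "LEFT_HIPPOCAMPUS",
    "RIGHT_HIPPOCAMPUS",
    "read_nifti",
    "write_nifti",
    "read_mask",
    "read_transform",
    "write_transform",
    "resample_mask",
]

#: conventional structure labels for hippocampal segmentations
LEFT_HIPPOCAMPUS = 1
RIGHT_HIPPOCAMPUS = 2

_RIGID_TOL = 1e-6


class FormatError(ValueError):
    """Raised when an input file is not a valid NIfTI-1 volume or transform."""


class GridMismatchError(ValueError):
    """Raised when two images expected to share a grid do not."""


@dataclass
class VolumetricImage:
    """A 3-D scalar volume with a voxel-index -> world-mm affine."""

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.voxels.ndim}")
        if min(self.voxels.shape) < 1:
            raise ValueError("every grid dimension must be >= 1")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_grid(self, other: "VolumetricImage", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class LabelMask(VolumetricImage):
    """A volume of non-negative integer labels (0 = background)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.voxels.dtype, np.integer):
            rounded = np.rint(self.voxels)
            if not np.array_equal(rounded, self.voxels):
                raise ValueError("label mask contains non-integer values")
            self.voxels = rounded.astype(np.int32)
        if self.voxels.size and self.voxels.min() < 0:
            raise ValueError("label mask contains negative labels")

    def labels(self) -> np.ndarray:
        """Sorted non-background labels present in the mask."""
        present = np.unique(self.voxels)
        return present[present > 0]

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.voxels == label))


@dataclass
class RigidTransform:
    """A 4x4 rigid (rotation + translation) world-mm -> world-mm transform."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("rigid transform must be a 4x4 matrix")
        if not np.allclose(self.matrix[3], [0.0, 0.0, 0.0, 1.0], atol=_RIGID_TOL):
            raise ValueError("last row of a rigid transform must be [0 0 0 1]")
        r = self.matrix[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=_RIGID_TOL):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation block has negative determinant (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_translation(cls, t: tuple[float, float, float]) -> "RigidTransform":
        m = np.eye(4)
        m[:3, 3] = t
        return cls(m)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(np.linalg.inv(self.matrix))


def read_nifti(path: str | Path) -> VolumetricImage:
    """Read a NIfTI-1 volume; trailing singleton dimensions are squeezed.

    Raises :class:`FormatError` for non-NIfTI payloads and :class:`ValueError`
    for volumes with more than three non-singleton dimensions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"{path} is not a readable NIfTI-1 file: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim > 3:
        extra = data.shape[3:]
        if any(s != 1 for s in extra):
            raise ValueError(
                f"{path}: expected a 3-D volume, got shape {data.shape}"
            )
        data = data.reshape(data.shape[:3])
    while data.ndim < 3:
        data = data[..., np.newaxis]
    return VolumetricImage(voxels=data, affine=np.asarray(img.affine))


def write_nifti(
    img: VolumetricImage, path: str | Path, description: str | None = None
) -> Path:
    """Write a volume as NIfTI-1, preserving the array datatype."""
    path = Path(path)
    nii = nib.Nifti1Image(img.voxels, img.affine)
    nii.set_data_dtype(img.voxels.dtype)
    if description is not None:
        nii.header["descrip"] = description.encode()[:79]
    nib.save(nii, path)
    return path


def read_mask(path: str | Path) -> LabelMask:
    img = read_nifti(path)
    return LabelMask(voxels=img.voxels, affine=img.affine)


def read_transform(path: str | Path) -> RigidTransform:
    """Read a 4-line whitespace-separated 4x4 world->world matrix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        matrix = np.loadtxt(path)
    except Exception as exc:
        raise FormatError(f"{path} is not a plain-text matrix: {exc}") from exc
    if matrix.shape != (4, 4):
        raise FormatError(f"{path}: expected a 4x4 matrix, got {matrix.shape}")
    return RigidTransform(matrix)


def write_transform(transform: RigidTransform, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, transform.matrix, fmt="%.10f")
    return path


def resample_mask(
    mask: LabelMask,
    transform: RigidTransform,
    reference: VolumetricImage,
    invert: bool = False,
) -> LabelMask:
    """Resample a label mask onto a reference grid through a rigid transform.

    Nearest-neighbour pull-back: each reference voxel centre is mapped to
    world space, through the inverse of ``transform`` (source-world ->
    target-world convention; pass ``invert=True`` if the stored matrix is the
    reverse), then into the source voxel grid, and the nearest source voxel's
    label is taken.  No fractional labels are ever produced.
    """
    world_to_world = transform.matrix if not invert else transform.inverse().matrix
    # reference index -> ref world -> source world -> source index
    index_map = (
        np.linalg.inv(mask.affine) @ np.linalg.inv(world_to_world) @ reference.affine
    )
    nx, ny, nz = reference.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    idx = np.stack([ii, jj, kk, np.ones_like(ii)], axis=0).reshape(4, -1)
    src = index_map @ idx
    src_idx = np.rint(src[:3]).astype(np.int64)
    inside = (
        (src_idx[0] >= 0)
        & (src_idx[0] < mask.shape[0])
        & (src_idx[1] >= 0)
        & (src_idx[1] < mask.shape[1])
        & (src_idx[2] >= 0)
        & (src_idx[2] < mask.shape[2])
    )
    out = np.zeros(nx * ny * nz, dtype=mask.voxels.dtype)
    out[inside] = mask.voxels[
        src_idx[0, inside], src_idx[1, inside], src_idx[2, inside]
    ]
    out = out.reshape(nx, ny, nz)
    if mask.voxels.any() and not out.any():
        warnings.warn(
            "resampled mask is empty: no overlap between the transformed mask "
            "and the reference field of view",
            stacklevel=2,
        )
    return LabelMask(voxels=out, affine=reference.affine.copy())
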