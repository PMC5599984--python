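"""Closed-form voxelwise T2 mapping from a dual-echo acquisition.

A dual-echo fast spin echo sequence samples the transverse decay
S(TE) = A * exp(-TE / T2) at two echo times TE1 < TE2 (the protocol this
package targets uses TE 30/119 msec).  With exactly two points the
monoexponential fit has the closed form

    T2 = (TE2 - TE1) / ln(S1 / S2)

which is exact wherever the signal actually decays (S1 > S2 > 0).  Voxels
violating that — zero or negative magnitude, or non-decaying signal, both of
which occur in background and at low SNR — have no defined T2 and are
carried in a validity mask rather than clamped or raised on.  A hard ceiling
(default 3000 msec) additionally marks voxels invalid so downstream
statistics stay finite; the ceiling comfortably exceeds CSF T2 at 3T.

Computation is double precision; on disk T2 maps are stored as float32
NIfTI with msec noted in the header, with a companion uint8 validity mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .image_core import GridMismatchError, VolumetricImage, write_nifti

__all__ = ["DualEchoAcquisition", "T2Map", "fit_t2_map", "predict_signal",
           "write_t2_map"]

DEFAULT_TE1_MS = 30.0
DEFAULT_TE2_MS = 119.0
DEFAULT_MAX_T2_MS = 3000.0


@dataclass
class DualEchoAcquisition:
    """Paired echo images sharing one grid, with their echo times in msec."""

    s1: VolumetricImage
    s2: VolumetricImage
    te1: float = DEFAULT_TE1_MS
    te2: float = DEFAULT_TE2_MS

    def __post_init__(self) -> None:
        if not self.s1.same_grid(self.s2):
            raise GridMismatchError("echo images do not share grid and affine")
        if not (0 < self.te1 < self.te2):
            raise ValueError(f"require 0 < te1 < te2, got {self.te1}/{self.te2}")


@dataclass
class T2Map:
    """Per-voxel T2 in msec plus a mask of voxels where the fit is defined.

    Invalid voxels hold NaN in ``t2`` and are excluded from all statistics.
    """

    t2: VolumetricImage
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.t2.shape:
            raise GridMismatchError("validity mask does not match the T2 grid")

    @property
    def affine(self) -> np.ndarray:
        return self.t2.affine

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t2.shape

    def values(self) -> np.ndarray:
        """T2 values of valid voxels only (1-D)."""
        return self.t2.voxels[self.valid]


def predict_signal(a, t2, te):
    """Forward monoexponential model ``a * exp(-te / t2)``.

    Used by the phantom generator and as the fit's round-trip oracle.
    Broadcasts over array inputs; ``t2`` must be strictly positive.
    """
    a = np.asarray(a, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    te = np.asarray(te, dtype=float)
    if np.any(t2 <= 0):
        raise ValueError("t2 must be strictly positive")
    if np.any(a < 0) or np.any(te < 0):
        raise ValueError("amplitude and echo time must be non-negative")
    return a * np.exp(-te / t2)


def fit_t2_map(
    acq: DualEchoAcquisition, max_t2: float = DEFAULT_MAX_T2_MS
) -> T2Map:
    """Closed-form dual-echo T2 fit, voxel by voxel.

    T2 = (te2 - te1) / ln(s1/s2) where s1 > s2 > 0; all other voxels (and
    any fitted value above ``max_t2``) are marked invalid, never raised on.
    """
    s1 = np.asarray(acq.s1.voxels, dtype=np.float64)
    s2 = np.asarray(acq.s2.voxels, dtype=np.float64)
    decaying = (s1 > 0) & (s2 > 0) & (s1 > s2)
    t2 = np.full(s1.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2[decaying] = (acq.te2 - acq.te1) / np.log(s1[decaying] / s2[decaying])
    valid = decaying & (t2 <= max_t2)
    t2[~valid] = np.nan
    return T2Map(
        t2=VolumetricImage(voxels=t2, affine=acq.s1.affine.copy()), valid=valid
    )


def write_t2_map(t2map: T2Map, path: str | Path, mask_path: str | Path | None = None):
    """Write the T2 map as float32 NIfTI (msec) and optionally its mask."""
    out = VolumetricImage(
        voxels=t2map.t2.voxels.astype(np.float32), affine=t2map.affine
    )
    write_nifti(out, path, description="T2 map (msec)")
    if mask_path is not None:
        mask = VolumetricImage(
            voxels=t2map.valid.astype(np.uint8), affine=t2map.affine
        )
        write_nifti(mask, mask_path, description="T2 fit validity mask")
    return Path(path)
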