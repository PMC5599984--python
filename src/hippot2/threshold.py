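"""Empirical calibration of the CSF-exclusion T2 cutoff.

The shipped default cutoff is 170 msec, appropriate for a dual-echo fast
spin echo protocol at 3T.  For other scanners or sequences the cutoff can be
re-derived from healthy-control data: T2 values are pooled per tissue class
(gray matter, white matter, CSF) using a tissue segmentation resampled onto
the T2-map grid, and the cutoff is placed between the upper tail of the gray
matter distribution and the lower tail of the CSF distribution.

"Between the tails" is operationalised as the value minimising the total
misclassification fraction (GM above the cutoff, which would be wrongly
removed from an ROI, plus CSF below it, which would be wrongly retained),
searched on a 1 msec grid between the GM and CSF medians with ties broken
toward the lower candidate.  Calibration is pooled across control subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_core import GridMismatchError, LabelMask
from .relaxometry import T2Map

__all__ = [
    "TissueSamples",
    "ThresholdResult",
    "CalibrationError",
    "TISSUE_LABELS",
    "collect_tissue_t2",
    "labels_from_probabilities",
    "calibrate_cutoff",
]

#: default label table for tissue-class masks
TISSUE_LABELS = {"gm": 1, "wm": 2, "csf": 3}

MIN_SAMPLES_PER_CLASS = 100


class CalibrationError(ValueError):
    """Raised when tissue distributions do not admit a cutoff."""


@dataclass
class TissueSamples:
    """Valid-voxel T2 samples grouped by tissue class (msec)."""

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray

    def __post_init__(self) -> None:
        for name in ("gm", "wm", "csf"):
            arr = np.asarray(getattr(self, name), dtype=float).ravel()
            if arr.size == 0:
                raise CalibrationError(f"no T2 samples for tissue class {name!r}")
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"{name} samples must be positive and finite")
            setattr(self, name, arr)

    @classmethod
    def concatenate(cls, parts: list["TissueSamples"]) -> "TissueSamples":
        return cls(
            gm=np.concatenate([p.gm for p in parts]),
            wm=np.concatenate([p.wm for p in parts]),
            csf=np.concatenate([p.csf for p in parts]),
        )


@dataclass
class ThresholdResult:
    """Calibrated cutoff and the residual tail fractions at that cutoff."""

    cutoff: float
    gm_tail_fraction: float
    csf_tail_fraction: float
    n_gm: int
    n_csf: int


def collect_tissue_t2(
    tissue_labels: LabelMask,
    t2map: T2Map,
    label_table: dict[str, int] = TISSUE_LABELS,
) -> TissueSamples:
    """Group valid-voxel T2 values by tissue class.

    The tissue mask must already sit on the T2-map grid (the rigid transform
    is applied upstream).  Invalid fit voxels are dropped; a class with no
    voxels in the mask, or none valid, is a calibration error.
    """
    if tissue_labels.shape != t2map.shape:
        raise GridMismatchError("tissue labels and T2 map are not on the same grid")
    out = {}
    for name in ("gm", "wm", "csf"):
        label = label_table[name]
        in_class = tissue_labels.voxels == label
        if not in_class.any():
            raise CalibrationError(f"tissue class {name!r} (label {label}) absent")
        vals = t2map.t2.voxels[in_class & t2map.valid]
        if vals.size == 0:
            raise CalibrationError(f"no valid T2 samples in class {name!r}")
        out[name] = vals
    return TissueSamples(**out)


def labels_from_probabilities(
    gm_prob: np.ndarray,
    wm_prob: np.ndarray,
    csf_prob: np.ndarray,
    affine: np.ndarray,
    min_probability: float = 0.9,
) -> LabelMask:
    """Hard tissue labels from probability maps.

    Only voxels where one class exceeds ``min_probability`` are labelled —
    a deliberate guard that keeps partial-volume voxels out of the
    calibration samples.
    """
    stacked = np.stack([gm_prob, wm_prob, csf_prob])
    winner = np.argmax(stacked, axis=0)
    confident = np.max(stacked, axis=0) > min_probability
    labels = np.where(confident, winner + 1, 0).astype(np.int16)
    return LabelMask(voxels=labels, affine=affine)


def calibrate_cutoff(
    samples: TissueSamples, grid_step: float = 1.0
) -> ThresholdResult:
    """Minimum-misclassification cutoff between GM and CSF T2 distributions.

    Grid search at ``grid_step`` msec over [GM median, CSF median]; the loss
    at candidate c is mean(gm > c) + mean(csf < c).  Ties go to the lowest
    candidate.  Requires >= 100 samples per class and separated medians.
    """
    gm, csf = samples.gm, samples.csf
    if gm.size < MIN_SAMPLES_PER_CLASS or csf.size < MIN_SAMPLES_PER_CLASS:
        raise CalibrationError(
            f"need >= {MIN_SAMPLES_PER_CLASS} samples per class, "
            f"got gm={gm.size}, csf={csf.size}"
        )
    gm_med, csf_med = float(np.median(gm)), float(np.median(csf))
    if gm_med >= csf_med:
        raise CalibrationError(
            f"GM median ({gm_med:.1f}) not below CSF median ({csf_med:.1f}); "
            "classes are not separable"
        )
    candidates = np.arange(np.ceil(gm_med), csf_med + grid_step / 2, grid_step)
    if candidates.size == 0:
        candidates = np.array([gm_med])
    gm_sorted, csf_sorted = np.sort(gm), np.sort(csf)
    gm_above = 1.0 - np.searchsorted(gm_sorted, candidates, side="right") / gm.size
    csf_below = np.searchsorted(csf_sorted, candidates, side="left") / csf.size
    loss = gm_above + csf_below
    best = int(np.argmin(loss))  # argmin takes the first, i.e. lowest, tie
    return ThresholdResult(
        cutoff=float(candidates[best]),
        gm_tail_fraction=float(gm_above[best]),
        csf_tail_fraction=float(csf_below[best]),
        n_gm=int(gm.size),
        n_csf=int(csf.size),
    )
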