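"""Digital phantoms and synthetic cohorts for end-to-end validation.

No public imaging archive carries the dual-echo hippocampal protocol this
package targets, so validation runs on synthetic data with known ground
truth, at two levels:

**Image level** — :func:`generate_phantom` builds a brain-like geometry on a
coronal grid (default 128 x 128 x 32 voxels at 0.43 x 0.43 x 4 mm, a 4x
in-plane downscale of the 512 x 512 acquisition matrix): a white-matter
core, a gray-matter rim, two hippocampal ellipsoids whose long axis runs
along the slice (anteroposterior) direction, and a CSF sheet wrapped
immediately around each hippocampus so that partial-volume contamination is
present by construction.  Dual-echo signals follow S(TE) = PD*exp(-TE/T2)
per compartment with Rician noise (magnitude MRI: the noisy signal is
sqrt((S+g1)^2 + g2^2) with g1, g2 ~ N(0, sigma)), approximately Gaussian at
high SNR and positively biased near zero signal.  The returned
"segmentation" deliberately overreaches one dilation step into the CSF
sheet, emulating a structural-image segmentation whose boundary voxels
straddle the hippocampus/CSF interface; truth labels and the noise-free T2
volume come along for oracle checks.

**Cohort level** — :func:`generate_cohort` draws per-hippocampus (corrected
volume, mean T2) feature rows from per-group Gaussian parameters; defaults
are the bundled normative group statistics (controls n=50, left HS n=27,
right HS n=18, bilateral HS n=5).  Left/right values of a subject are
correlated (default 0.3) purely for realism.

:func:`simulate_manual_rois` emulates the legacy manual workflow — a small
elliptical ROI (about 20 mm^2) placed per coronal slice near the structure
centroid with operator placement jitter — whose CSF-inclusion errors the
automated whole-structure method is designed to beat.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import reference_data
from .image_core import (
    LEFT_HIPPOCAMPUS,
    RIGHT_HIPPOCAMPUS,
    LabelMask,
    VolumetricImage,
)
from .relaxometry import DualEchoAcquisition, T2Map, predict_signal

__all__ = [
    "PhantomSpec",
    "PhantomData",
    "CohortSpec",
    "ManualRoiResult",
    "LABELS",
    "generate_phantom",
    "generate_cohort",
    "simulate_manual_rois",
    "tissue_label_mask",
]

#: phantom compartment label table (hippocampi match the segmentation
#: convention of :mod:`hippot2.image_core`)
LABELS = {
    "background": 0,
    "left_hippocampus": LEFT_HIPPOCAMPUS,
    "right_hippocampus": RIGHT_HIPPOCAMPUS,
    "gm": 3,
    "wm": 4,
    "csf": 5,
}

MIN_HIPPOCAMPUS_VOXELS = 500


@dataclass
class PhantomSpec:
    """Geometry, tissue properties and noise of one digital phantom.

    Default T2 values are typical 3T figures: WM 80, GM 110, hippocampus
    115, CSF 2000 msec.  ``noise_sigma=5`` with the default proton
    densities puts the late-echo hippocampal SNR near 55.
    ``t2_hippocampus_anterior/posterior``, when both set, impose a step
    profile along the slice axis (anterior = lower slice index).
    ``segmentation_dilation`` controls how far the returned segmentation
    overreaches into the CSF sheet (0 = perfect segmentation).
    """

    shape: tuple[int, int, int] = (128, 128, 32)
    voxel_size: tuple[float, float, float] = (0.43, 0.43, 4.0)
    t2: dict = field(
        default_factory=lambda: {
            "wm": 80.0, "gm": 110.0, "hippocampus": 115.0, "csf": 2000.0
        }
    )
    proton_density: dict = field(
        default_factory=lambda: {
            "wm": 700.0, "gm": 800.0, "hippocampus": 800.0, "csf": 1000.0
        }
    )
    te1: float = reference_data.DEFAULT_TE1_MS
    te2: float = reference_data.DEFAULT_TE2_MS
    noise_sigma: float = 5.0
    t2_hippocampus_left: float | None = None
    t2_hippocampus_right: float | None = None
    t2_hippocampus_anterior: float | None = None
    t2_hippocampus_posterior: float | None = None
    segmentation_dilation: int = 1
    seed: int = 0

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([*self.voxel_size, 1.0])
        return aff


@dataclass
class PhantomData:
    """Ground truth plus simulated acquisition for one phantom."""

    truth_labels: LabelMask
    truth_t2: VolumetricImage
    acquisition: DualEchoAcquisition
    segmentation: LabelMask
    spec: PhantomSpec

    def truth_t2_map(self) -> T2Map:
        """The noise-free T2 volume wrapped as a map (background invalid)."""
        valid = self.truth_t2.voxels > 0
        t2 = np.where(valid, self.truth_t2.voxels, np.nan)
        return T2Map(
            t2=VolumetricImage(voxels=t2, affine=self.truth_t2.affine.copy()),
            valid=valid,
        )


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _build_geometry(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.shape
    labels = np.zeros(spec.shape, dtype=np.int16)
    brain = _ellipsoid(
        spec.shape,
        (nx / 2 - 0.5, ny / 2 - 0.5, nz / 2 - 0.5),
        (0.46 * nx, 0.46 * ny, 0.46 * nz),
    )
    labels[brain] = LABELS["wm"]
    # cortical gray-matter rim: outer two-voxel shell of the brain
    rim = brain & ~ndimage.binary_erosion(brain, iterations=2)
    labels[rim] = LABELS["gm"]

    semi = (max(3, nx // 12), max(4, ny // 9), max(2, nz // 6))
    conn6 = ndimage.generate_binary_structure(3, 1)
    for side, cx in (("left_hippocampus", 0.32), ("right_hippocampus", 0.68)):
        hippo = _ellipsoid(
            spec.shape, (cx * nx, ny / 2 - 0.5, nz / 2 - 0.5), semi
        )
        n_hippo = int(hippo.sum())
        if n_hippo < MIN_HIPPOCAMPUS_VOXELS:
            raise ValueError(
                f"grid {spec.shape} too small: {side} has {n_hippo} voxels "
                f"(< {MIN_HIPPOCAMPUS_VOXELS})"
            )
        sheet = ndimage.binary_dilation(hippo, structure=conn6) & ~hippo
        # deeper GM cuff between the CSF sheet and white matter
        cuff = (
            ndimage.binary_dilation(hippo, structure=conn6, iterations=4)
            & ~hippo
            & ~sheet
        )
        labels[cuff] = LABELS["gm"]
        labels[sheet] = LABELS["csf"]
        labels[hippo] = LABELS[side]
    return labels


def _truth_t2_volume(spec: PhantomSpec, labels: np.ndarray) -> np.ndarray:
    t2 = np.zeros(spec.shape, dtype=float)
    for tissue in ("wm", "gm", "csf"):
        t2[labels == LABELS[tissue]] = spec.t2[tissue]
    for side, override in (
        ("left_hippocampus", spec.t2_hippocampus_left),
        ("right_hippocampus", spec.t2_hippocampus_right),
    ):
        value = override if override is not None else spec.t2["hippocampus"]
        t2[labels == LABELS[side]] = value
    if (
        spec.t2_hippocampus_anterior is not None
        and spec.t2_hippocampus_posterior is not None
    ):
        hippo = (labels == LEFT_HIPPOCAMPUS) | (labels == RIGHT_HIPPOCAMPUS)
        k = np.arange(spec.shape[2])[None, None, :]
        anterior = np.broadcast_to(k < spec.shape[2] // 2, spec.shape)
        t2[hippo & anterior] = spec.t2_hippocampus_anterior
        t2[hippo & ~anterior] = spec.t2_hippocampus_posterior
    return t2


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator):
    if sigma == 0:
        return signal.copy()
    g1 = rng.normal(0.0, sigma, signal.shape)
    g2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + g1) ** 2 + g2**2)


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomData:
    """Build geometry, forward-model the two echoes, add Rician noise."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    labels = _build_geometry(spec)
    truth_t2 = _truth_t2_volume(spec, labels)

    pd_map = np.zeros(spec.shape, dtype=float)
    for tissue in ("wm", "gm", "csf"):
        pd_map[labels == LABELS[tissue]] = spec.proton_density[tissue]
    hippo = (labels == LEFT_HIPPOCAMPUS) | (labels == RIGHT_HIPPOCAMPUS)
    pd_map[hippo] = spec.proton_density["hippocampus"]

    inside = truth_t2 > 0
    s1 = np.zeros(spec.shape)
    s2 = np.zeros(spec.shape)
    s1[inside] = predict_signal(pd_map[inside], truth_t2[inside], spec.te1)
    s2[inside] = predict_signal(pd_map[inside], truth_t2[inside], spec.te2)
    s1 = _rician(s1, spec.noise_sigma, rng)
    s2 = _rician(s2, spec.noise_sigma, rng)

    affine = spec.affine
    seg = np.zeros(spec.shape, dtype=np.int16)
    conn6 = ndimage.generate_binary_structure(3, 1)
    csf = labels == LABELS["csf"]
    for label in (LEFT_HIPPOCAMPUS, RIGHT_HIPPOCAMPUS):
        structure = labels == label
        if spec.segmentation_dilation > 0:
            overreach = (
                ndimage.binary_dilation(
                    structure, structure=conn6,
                    iterations=spec.segmentation_dilation,
                )
                & csf
            )
            structure = structure | overreach
        seg[structure] = label

    return PhantomData(
        truth_labels=LabelMask(voxels=labels, affine=affine.copy()),
        truth_t2=VolumetricImage(voxels=truth_t2, affine=affine.copy()),
        acquisition=DualEchoAcquisition(
            s1=VolumetricImage(voxels=s1, affine=affine.copy()),
            s2=VolumetricImage(voxels=s2, affine=affine.copy()),
            te1=spec.te1,
            te2=spec.te2,
        ),
        segmentation=LabelMask(voxels=seg, affine=affine.copy()),
        spec=spec,
    )


def tissue_label_mask(phantom: PhantomData) -> LabelMask:
    """GM/WM/CSF labels (1/2/3) for threshold calibration, hippocampi as GM."""
    src = phantom.truth_labels.voxels
    out = np.zeros_like(src)
    out[src == LABELS["gm"]] = 1
    out[(src == LEFT_HIPPOCAMPUS) | (src == RIGHT_HIPPOCAMPUS)] = 1
    out[src == LABELS["wm"]] = 2
    out[src == LABELS["csf"]] = 3
    return LabelMask(voxels=out, affine=phantom.truth_labels.affine.copy())


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class CohortSpec:
    """Per-group Gaussian feature parameters for synthetic cohorts.

    ``groups`` maps a group name to ``{"n": int, "left"/"right":
    {"volume": (mean, sd), "t2": (mean, sd)}}``; the default reproduces the
    bundled normative cohort.  ``cross_side_corr`` correlates a subject's
    left and right values of each feature.
    """

    groups: dict = field(
        default_factory=lambda: {
            k: {
                "n": v["n"],
                "left": dict(v["left"]),
                "right": dict(v["right"]),
            }
            for k, v in reference_data.COHORT_GROUPS.items()
        }
    )
    cross_side_corr: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.cross_side_corr <= 1.0:
            raise ValueError("cross_side_corr must be in [-1, 1]")
        for name, grp in self.groups.items():
            if grp["n"] < 1:
                raise ValueError(f"group {name!r} has n < 1")
            for side in ("left", "right"):
                for feat in ("volume", "t2"):
                    if grp[side][feat][1] < 0:
                        raise ValueError(
                            f"negative SD for {name}/{side}/{feat}"
                        )


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw per-hippocampus feature rows for every group.

    Returns a tidy frame with columns subject_id, group, side,
    corrected_volume_cm3, mean_t2_ms; one row per hippocampus.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    rho = spec.cross_side_corr
    rows = []
    sid = 0
    for group, params in spec.groups.items():
        for _ in range(params["n"]):
            sid += 1
            values = {}
            for feat in ("volume", "t2"):
                zl = rng.standard_normal()
                zr = rho * zl + np.sqrt(1 - rho**2) * rng.standard_normal()
                for side, z in (("left", zl), ("right", zr)):
                    mean, sd = params[side][feat]
                    values[(side, feat)] = mean + sd * z
            for side in ("left", "right"):
                rows.append(
                    {
                        "subject_id": f"sub-{sid:04d}",
                        "group": group,
                        "side": side,
                        "corrected_volume_cm3": values[(side, "volume")],
                        "mean_t2_ms": values[(side, "t2")],
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# manual-ROI emulation


@dataclass
class ManualRoiResult:
    """Outcome of simulated manual elliptical-ROI sampling."""

    mean_t2: float
    slice_index: np.ndarray
    mean_t2_per_slice: np.ndarray
    n_voxels: int


def simulate_manual_rois(
    mask: LabelMask,
    t2map: T2Map,
    label: int,
    roi_area_mm2: float = 20.0,
    jitter_mm: float = 1.0,
    margin: float = 0.9,
    min_area_factor: float = 1.5,
    slice_axis: int = 2,
    seed: int | np.random.Generator = 0,
) -> ManualRoiResult:
    """Emulate manual elliptical-ROI T2 reading on consecutive coronal slices.

    On each slice whose structure cross-section can host the ROI, an
    ellipse of ``roi_area_mm2`` is placed at the structure's in-plane
    centroid plus Gaussian placement jitter of SD ``jitter_mm`` per axis.
    The ellipse copies the cross-section's own shape (semi-axes from the
    in-plane coordinate spread, rescaled to the target area and shrunk by
    ``margin``), the way a rater moulds a small ROI to the structure;
    slices whose cross-section is below ``min_area_factor`` times the ROI
    area are skipped, as a rater avoids slices where the ROI barely fits.  All ellipse voxels with a
    valid fit contribute — including any CSF a jittered ellipse strays
    into, which is exactly the operator error the automated method avoids.
    The reported value is the voxel-pooled mean over all sampled slices.
    """
    if slice_axis != 2:
        raise NotImplementedError("manual ROI simulation assumes slice axis 2")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    structure = mask.voxels == label
    if not structure.any():
        raise ValueError(f"structure {label} absent from the mask")
    vx, vy = mask.voxel_size[0], mask.voxel_size[1]
    nx, ny, _ = mask.shape
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")

    slice_ids, slice_means, slice_counts = [], [], []
    for k in range(mask.shape[2]):
        in_slice = structure[:, :, k]
        area_mm2 = float(in_slice.sum()) * vx * vy
        if area_mm2 < min_area_factor * roi_area_mm2:
            continue  # a rater skips slices where the ROI barely fits
        ci, cj = ndimage.center_of_mass(in_slice)
        # cross-section semi-axes from the coordinate spread (ellipse: 2*sd)
        xi, yj = np.nonzero(in_slice)
        a_vox = 2.0 * float(np.std(xi))
        b_vox = 2.0 * float(np.std(yj))
        if a_vox == 0 or b_vox == 0:
            continue
        scale = margin * np.sqrt(
            roi_area_mm2 / (np.pi * a_vox * vx * b_vox * vy)
        )
        a_vox *= scale
        b_vox *= scale
        ci += rng.normal(0.0, jitter_mm) / vx
        cj += rng.normal(0.0, jitter_mm) / vy
        ellipse = ((ii - ci) / a_vox) ** 2 + ((jj - cj) / b_vox) ** 2 <= 1.0
        usable = ellipse & t2map.valid[:, :, k]
        if not usable.any():
            continue
        vals = t2map.t2.voxels[:, :, k][usable]
        slice_ids.append(k)
        slice_means.append(float(np.mean(vals)))
        slice_counts.append(int(vals.size))
    if not slice_ids:
        raise ValueError(f"no usable manual-ROI voxels for structure {label}")
    counts = np.asarray(slice_counts)
    means = np.asarray(slice_means)
    return ManualRoiResult(
        mean_t2=float(np.sum(means * counts) / np.sum(counts)),
        slice_index=np.asarray(slice_ids),
        mean_t2_per_slice=means,
        n_voxels=int(counts.sum()),
    )
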