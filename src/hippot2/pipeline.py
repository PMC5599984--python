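"""End-to-end orchestration: per-subject measurement and cohort statistics.

A subject is measured by the fixed chain

    fit T2 map -> resample segmentation -> erode -> CSF-exclude ->
    summarise -> ICV-correct volume -> flag against reference ranges
    (-> classifier probability, when a fitted classifier is supplied)

and a cohort run maps that over a manifest, then derives group-comparison
tables, normative reference ranges from the controls, per-side logistic
classifiers, and (when repeat scans are present) Bland-Altman scan-rescan
agreement.

Stage failures are wrapped in :class:`StageError` carrying the stage name
and subject id; in batch mode the cohort runner records the failure and
moves on to the next subject.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, reference_data
from .image_core import (
    LEFT_HIPPOCAMPUS,
    RIGHT_HIPPOCAMPUS,
    LabelMask,
    RigidTransform,
    read_mask,
    read_nifti,
    read_transform,
    resample_mask,
)
from .relaxometry import (
    DEFAULT_MAX_T2_MS,
    DualEchoAcquisition,
    fit_t2_map,
    write_t2_map,
)
from .roi import RoiMeasurement, RoiPolicy, measure_roi
from .stats import (
    ClassifierModel,
    GroupStats,
    classify,
    fit_logistic,
    paired_comparison,
    pooled_bilateral_stats,
    reference_range,
    training_accuracy,
    two_sample_t,
)
from .volumetry import VolumeRecord, VolumetryModel, correct_volume

__all__ = [
    "PipelineConfig",
    "SubjectRecord",
    "SideResult",
    "SubjectReport",
    "StageError",
    "run_subject",
    "run_cohort",
    "cohort_statistics",
    "default_reference_ranges",
]

SIDE_LABELS = {"left": LEFT_HIPPOCAMPUS, "right": RIGHT_HIPPOCAMPUS}


class StageError(RuntimeError):
    """A pipeline stage failed for one subject."""

    def __init__(self, stage: str, subject_id: str, cause: Exception):
        self.stage = stage
        self.subject_id = subject_id
        self.cause = cause
        super().__init__(f"[{subject_id}] stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """All tunables of the measurement chain, loadable from YAML."""

    te1: float = reference_data.DEFAULT_TE1_MS
    te2: float = reference_data.DEFAULT_TE2_MS
    max_t2: float = DEFAULT_MAX_T2_MS
    csf_threshold: float = reference_data.DEFAULT_CSF_THRESHOLD_MS
    erosion_iterations: int = 1
    erosion_mode: str = "in-plane"
    min_voxels: int = 20
    slice_axis: int = 2
    invert_transform: bool = False
    seed: int = 0

    def roi_policy(self) -> RoiPolicy:
        return RoiPolicy(
            erosion_iterations=self.erosion_iterations,
            erosion_mode=self.erosion_mode,
            csf_threshold=self.csf_threshold,
            min_voxels=self.min_voxels,
            slice_axis=self.slice_axis,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def default_reference_ranges() -> dict[str, Any]:
    """Normative ranges derived from the bundled control statistics.

    Reported at the conventional precision: 0.1 msec for T2, 0.01 cm^3 for
    volumes.  T2 ranges are given per side and pooled bilaterally; the
    volume range pools both sides.
    """
    out: dict[str, Any] = {}
    t2_sides = {}
    vol_sides = {}
    for side in ("left", "right"):
        t2_sides[side] = GroupStats(*reference_data.control_stats(side, "t2"))
        vol_sides[side] = GroupStats(*reference_data.control_stats(side, "volume"))
        rr = reference_range(t2_sides[side]).rounded(1)
        out[f"t2_range_{side}"] = {"lower": rr.lower, "upper": rr.upper}
    t2_pooled = reference_range(
        pooled_bilateral_stats(t2_sides["left"], t2_sides["right"])
    ).rounded(1)
    vol_pooled = reference_range(
        pooled_bilateral_stats(vol_sides["left"], vol_sides["right"])
    ).rounded(2)
    out["t2_range"] = {"lower": t2_pooled.lower, "upper": t2_pooled.upper}
    out["volume_range"] = {"lower": vol_pooled.lower, "upper": vol_pooled.upper}
    return out


@dataclass
class SubjectRecord:
    """File paths and scalar inputs for one subject."""

    subject_id: str
    s1_path: str
    s2_path: str
    seg_path: str
    transform_path: str | None = None
    icv_cm3: float | None = None
    group: str | None = None
    s1_repeat_path: str | None = None
    s2_repeat_path: str | None = None


@dataclass
class SideResult:
    side: str
    measurement: RoiMeasurement
    raw_volume_cm3: float
    corrected_volume_cm3: float | None = None
    t2_flag: str | None = None
    volume_flag: str | None = None
    pathologic_probability: float | None = None


@dataclass
class SubjectReport:
    subject_id: str
    sides: dict[str, SideResult]
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_rows(self) -> list[dict[str, Any]]:
        rows = []
        for side, res in self.sides.items():
            m = res.measurement
            rows.append(
                {
                    "subject_id": self.subject_id,
                    "side": side,
                    "n_voxels": m.n_voxels,
                    "n_excluded_csf": m.n_excluded_csf,
                    "n_invalid": m.n_invalid,
                    "mean_t2_ms": m.mean_t2,
                    "sd_t2_ms": m.sd_t2,
                    "raw_volume_cm3": res.raw_volume_cm3,
                    "corrected_volume_cm3": res.corrected_volume_cm3,
                    "t2_flag": res.t2_flag,
                    "volume_flag": res.volume_flag,
                    "pathologic_probability": res.pathologic_probability,
                    "flags": "" if m.reliable else "unreliable:few-voxels",
                }
            )
        return rows


def _measure_on_images(
    s1_path, s2_path, seg: LabelMask, transform: RigidTransform,
    config: PipelineConfig, subject_id: str,
    keep_intermediates: Path | None = None,
):
    """fit -> resample -> erode/exclude/summarise for one acquisition."""
    try:
        s1 = read_nifti(s1_path)
        s2 = read_nifti(s2_path)
    except Exception as exc:
        raise StageError("load-echoes", subject_id, exc) from exc
    try:
        acq = DualEchoAcquisition(s1=s1, s2=s2, te1=config.te1, te2=config.te2)
        t2map = fit_t2_map(acq, max_t2=config.max_t2)
    except Exception as exc:
        raise StageError("fit-t2", subject_id, exc) from exc
    try:
        resampled = resample_mask(
            seg, transform, s1, invert=config.invert_transform
        )
    except Exception as exc:
        raise StageError("resample", subject_id, exc) from exc
    try:
        measurements = measure_roi(resampled, t2map, config.roi_policy())
    except Exception as exc:
        raise StageError("roi-measure", subject_id, exc) from exc
    if keep_intermediates is not None:
        keep_intermediates.mkdir(parents=True, exist_ok=True)
        write_t2_map(
            t2map,
            keep_intermediates / f"{subject_id}_t2map.nii.gz",
            keep_intermediates / f"{subject_id}_t2valid.nii.gz",
        )
        from .image_core import write_nifti

        write_nifti(
            resampled, keep_intermediates / f"{subject_id}_roi.nii.gz"
        )
    return measurements


def run_subject(
    record: SubjectRecord,
    config: PipelineConfig = PipelineConfig(),
    volumetry_model: VolumetryModel | None = None,
    reference_ranges: dict[str, Any] | None = None,
    classifiers: dict[str, ClassifierModel] | None = None,
    keep_intermediates: str | Path | None = None,
) -> SubjectReport:
    """Measure one subject end to end.

    ``reference_ranges`` defaults to the bundled normative ranges; pass the
    output of a control-cohort fit to use study-specific ones.  Classifier
    probabilities are attached only when fitted per-side classifiers (with
    features (corrected volume, mean T2)) are supplied.
    """
    if reference_ranges is None:
        reference_ranges = default_reference_ranges()
    try:
        seg = read_mask(record.seg_path)
        transform = (
            read_transform(record.transform_path)
            if record.transform_path
            else RigidTransform.identity()
        )
    except Exception as exc:
        raise StageError("load-segmentation", record.subject_id, exc) from exc

    measurements = _measure_on_images(
        record.s1_path, record.s2_path, seg, transform, config,
        record.subject_id,
        Path(keep_intermediates) if keep_intermediates else None,
    )

    sides: dict[str, SideResult] = {}
    for side, label in SIDE_LABELS.items():
        if label not in measurements:
            continue
        raw_vol = seg.count(label) * seg.voxel_volume_mm3 / 1000.0
        corrected = None
        if volumetry_model is not None and record.icv_cm3 is not None:
            corrected = correct_volume(
                VolumeRecord(raw_volume=raw_vol, icv=record.icv_cm3),
                volumetry_model,
            )
        res = SideResult(
            side=side,
            measurement=measurements[label],
            raw_volume_cm3=raw_vol,
            corrected_volume_cm3=corrected,
        )
        t2_range = reference_ranges.get(f"t2_range_{side}") or reference_ranges.get(
            "t2_range"
        )
        if t2_range:
            res.t2_flag = _flag(measurements[label].mean_t2, t2_range)
        vol_for_flag = corrected if corrected is not None else None
        if vol_for_flag is not None and "volume_range" in reference_ranges:
            res.volume_flag = _flag(vol_for_flag, reference_ranges["volume_range"])
        if classifiers and side in classifiers and corrected is not None:
            prob, _ = classify(
                classifiers[side],
                np.array([[corrected, measurements[label].mean_t2]]),
            )
            res.pathologic_probability = float(prob[0])
        sides[side] = res

    return SubjectReport(
        subject_id=record.subject_id,
        sides=sides,
        provenance={
            "software": f"hippot2 {__version__}",
            "config_hash": config.config_hash(),
            "seed": config.seed,
        },
    )


def _flag(value: float, rng: dict[str, float]) -> str:
    if value < rng["lower"]:
        return "below"
    if value > rng["upper"]:
        return "above"
    return "within"


# ---------------------------------------------------------------------------
# cohort level


def cohort_statistics(
    features: pd.DataFrame, control_group: str = reference_data.CONTROL_GROUP
) -> dict[str, Any]:
    """Group table, normative ranges and classifiers from a feature table.

    ``features`` needs columns (subject_id, group, side,
    corrected_volume_cm3, mean_t2_ms), one row per hippocampus.
    """
    required = {"subject_id", "group", "side", "corrected_volume_cm3", "mean_t2_ms"}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"feature table lacks columns {sorted(missing)}")
    controls = features[features["group"] == control_group]
    if controls.empty:
        raise ValueError(f"no rows for control group {control_group!r}")

    measures = {"volume": "corrected_volume_cm3", "t2": "mean_t2_ms"}
    group_rows = []
    for side in ("left", "right"):
        for measure, col in measures.items():
            ctrl_vals = controls.loc[controls["side"] == side, col].to_numpy()
            for group in features["group"].unique():
                vals = features.loc[
                    (features["group"] == group) & (features["side"] == side), col
                ].to_numpy()
                row = {
                    "side": side,
                    "measure": measure,
                    "group": group,
                    "n": vals.size,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
                }
                if group != control_group and vals.size >= 2:
                    t, p = two_sample_t(vals, ctrl_vals)
                    row["t_vs_controls"], row["p_vs_controls"] = t, p
                group_rows.append(row)
    group_table = pd.DataFrame(group_rows)

    ranges: dict[str, Any] = {}
    side_stats = {m: {} for m in measures}
    for measure, col in measures.items():
        for side in ("left", "right"):
            stats = GroupStats.from_samples(
                controls.loc[controls["side"] == side, col].to_numpy()
            )
            side_stats[measure][side] = stats
            nd = 1 if measure == "t2" else 2
            rr = reference_range(stats).rounded(nd)
            ranges[f"{measure}_range_{side}"] = {
                "lower": rr.lower, "upper": rr.upper
            }
        pooled = pooled_bilateral_stats(
            side_stats[measure]["left"], side_stats[measure]["right"]
        )
        nd = 1 if measure == "t2" else 2
        rr = reference_range(pooled).rounded(nd)
        ranges[f"{measure}_range"] = {"lower": rr.lower, "upper": rr.upper}

    classifiers: dict[str, Any] = {}
    for side in ("left", "right"):
        sub = features[features["side"] == side]
        y = sub["group"].isin(reference_data.PATHOLOGIC_GROUPS[side]).to_numpy()
        y = y.astype(int)
        if min(np.sum(y == 0), np.sum(y == 1)) < 2:
            continue
        feats = {
            "volume": sub[["corrected_volume_cm3"]].to_numpy(),
            "t2": sub[["mean_t2_ms"]].to_numpy(),
            "combined": sub[["corrected_volume_cm3", "mean_t2_ms"]].to_numpy(),
        }
        names = {
            "volume": ("volume",), "t2": ("t2",), "combined": ("volume", "t2")
        }
        classifiers[side] = {}
        for kind, X in feats.items():
            model = fit_logistic(X, y, feature_names=names[kind])
            classifiers[side][kind] = {
                "model": model,
                "training_accuracy": training_accuracy(model, X, y),
            }

    return {
        "group_table": group_table,
        "reference_ranges": ranges,
        "classifiers": classifiers,
        "n_hippocampi": int(len(features)),
    }


def run_cohort(
    manifest: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
    control_group: str = reference_data.CONTROL_GROUP,
    fit_ranges: bool = True,
) -> dict[str, Any]:
    """Measure every subject in a manifest and derive cohort statistics.

    The manifest needs columns (subject_id, group, s1, s2, seg) plus
    optional transform, icv_cm3, s1_repeat, s2_repeat.  Per-subject stage
    failures are collected, not fatal.  The ICV model and (when
    ``fit_ranges``) the reference ranges are fitted on the manifest's
    controls; otherwise the bundled normative ranges apply.
    """
    if manifest.empty:
        raise ValueError("empty manifest")

    def _opt(row, key):
        val = row.get(key)
        if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
            return None
        return val

    records = []
    for _, row in manifest.iterrows():
        icv = _opt(row, "icv_cm3")
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                s1_path=row["s1"],
                s2_path=row["s2"],
                seg_path=row["seg"],
                transform_path=_opt(row, "transform"),
                icv_cm3=float(icv) if icv is not None else None,
                group=str(row["group"]) if "group" in row else None,
                s1_repeat_path=_opt(row, "s1_repeat"),
                s2_repeat_path=_opt(row, "s2_repeat"),
            )
        )

    # ICV model from controls with both volume inputs available
    volumetry_model = None
    ctrl = [r for r in records if r.group == control_group and r.icv_cm3]
    if len(ctrl) >= 3:
        vols, icvs = [], []
        for rec in ctrl:
            seg = read_mask(rec.seg_path)
            for label in SIDE_LABELS.values():
                if seg.count(label):
                    vols.append(seg.count(label) * seg.voxel_volume_mm3 / 1000.0)
                    icvs.append(rec.icv_cm3)
        if len(vols) >= 3 and np.var(icvs) > 0:
            from .volumetry import fit_icv_model

            volumetry_model = fit_icv_model(vols, icvs)

    reports: list[SubjectReport] = []
    failures: list[dict[str, str]] = []
    repeat_rows: list[dict[str, Any]] = []
    for rec in records:
        try:
            report = run_subject(
                rec, config, volumetry_model=volumetry_model
            )
        except StageError as err:
            failures.append(
                {"subject_id": err.subject_id, "stage": err.stage,
                 "error": str(err.cause)}
            )
            continue
        reports.append(report)
        if rec.s1_repeat_path and rec.s2_repeat_path:
            try:
                seg = read_mask(rec.seg_path)
                transform = (
                    read_transform(rec.transform_path)
                    if rec.transform_path
                    else RigidTransform.identity()
                )
                repeat = _measure_on_images(
                    rec.s1_repeat_path, rec.s2_repeat_path, seg, transform,
                    config, rec.subject_id,
                )
            except StageError as err:
                failures.append(
                    {"subject_id": err.subject_id, "stage": "repeat-" + err.stage,
                     "error": str(err.cause)}
                )
            else:
                for side, label in SIDE_LABELS.items():
                    if label in repeat and side in report.sides:
                        repeat_rows.append(
                            {
                                "subject_id": rec.subject_id,
                                "side": side,
                                "scan1": report.sides[side].measurement.mean_t2,
                                "scan2": repeat[label].mean_t2,
                            }
                        )

    rows = []
    group_of = {r.subject_id: r.group for r in records}
    for report in reports:
        for row in report.to_rows():
            row["group"] = group_of.get(row["subject_id"])
            rows.append(row)
    per_subject = pd.DataFrame(rows)

    result: dict[str, Any] = {
        "per_subject": per_subject,
        "reports": reports,
        "failures": failures,
    }
    if not per_subject.empty and "group" in per_subject:
        features = per_subject.rename(columns={"mean_t2_ms": "mean_t2_ms"})
        usable = features.dropna(subset=["corrected_volume_cm3"])
        if not usable.empty and (usable["group"] == control_group).any():
            try:
                result["statistics"] = cohort_statistics(
                    usable[
                        ["subject_id", "group", "side",
                         "corrected_volume_cm3", "mean_t2_ms"]
                    ],
                    control_group=control_group,
                )
            except ValueError:
                pass
    if repeat_rows:
        repeats = pd.DataFrame(repeat_rows)
        result["agreement"] = paired_comparison(
            repeats["scan1"].to_numpy(), repeats["scan2"].to_numpy()
        )
        result["repeat_measurements"] = repeats
    return result
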