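"""Head-size correction of hippocampal volumes.

Raw hippocampal volumes scale with head size, so group comparisons use
volumes corrected for intracranial volume (ICV) by the regression-residual
method: an ordinary least-squares slope b of volume on ICV is fitted in
healthy controls, and every subject's volume is adjusted to the control
mean ICV,

    corrected = raw - b * (ICV - mean ICV of controls).

Centering at the control ICV mean keeps corrected volumes on their natural
cm^3 scale and leaves the control-group mean volume unchanged; corrected
control volumes are uncorrelated with ICV by construction.  Left and right
hippocampi share a single pooled model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = ["VolumetryModel", "VolumeRecord", "fit_icv_model", "correct_volume"]


@dataclass
class VolumetryModel:
    """Control-derived ICV regression parameters (cm^3 units throughout)."""

    slope_b: float
    icv_mean_controls: float
    n_controls: int
    slope_se: float = float("nan")


@dataclass
class VolumeRecord:
    raw_volume: float
    icv: float
    corrected_volume: float | None = None

    def __post_init__(self) -> None:
        if self.raw_volume <= 0 or self.icv <= 0:
            raise ValueError("volumes must be positive")


def fit_icv_model(
    control_volumes, control_icvs
) -> VolumetryModel:
    """OLS slope of hippocampal volume on ICV in healthy controls."""
    vols = np.asarray(control_volumes, dtype=float)
    icvs = np.asarray(control_icvs, dtype=float)
    if vols.shape != icvs.shape or vols.ndim != 1:
        raise ValueError("control volumes and ICVs must be equal-length 1-D")
    if vols.size < 3:
        raise ValueError("need at least 3 controls to fit the ICV model")
    if np.var(icvs) == 0:
        raise ValueError("control ICVs are constant; slope is undefined")
    fit = sm.OLS(vols, sm.add_constant(icvs)).fit()
    return VolumetryModel(
        slope_b=float(fit.params[1]),
        icv_mean_controls=float(np.mean(icvs)),
        n_controls=int(vols.size),
        slope_se=float(fit.bse[1]),
    )


def correct_volume(record: VolumeRecord, model: VolumetryModel) -> float:
    """Adjust a raw volume to the control mean ICV."""
    corrected = record.raw_volume - model.slope_b * (
        record.icv - model.icv_mean_controls
    )
    record.corrected_volume = float(corrected)
    return record.corrected_volume
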