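"""Bundled normative statistics and default acquisition constants.

The defaults shipped here summarise a healthy-control cohort (n = 50) and
three hippocampal sclerosis (HS) patient groups scanned with a 3T epilepsy
protocol (coronal dual-echo fast recovery fast spin echo, TE 30/119 msec).
They drive three things:

* the default normative reference ranges (mean +/- 1.96 SD of the controls),
* the default parameters of the synthetic cohort generator, and
* the pathologic/nonpathologic labelling convention of the classifiers.

Volumes are ICV-corrected hippocampal volumes in cm^3; T2 values are
whole-hippocampus mean T2 in msec.  All entries are (mean, SD).
"""

from __future__ import annotations

DEFAULT_TE1_MS = 30.0
DEFAULT_TE2_MS = 119.0
DEFAULT_CSF_THRESHOLD_MS = 170.0

CONTROL_GROUP = "control"

#: per-group sample sizes and per-side (mean, SD) of corrected volume (cm^3)
#: and mean hippocampal T2 (msec)
COHORT_GROUPS: dict[str, dict] = {
    "control": {
        "n": 50,
        "left": {"volume": (3.02, 0.28), "t2": (115.5, 4.11)},
        "right": {"volume": (3.04, 0.25), "t2": (116.8, 3.60)},
    },
    "left_hs": {
        "n": 27,
        "left": {"volume": (2.05, 0.30), "t2": (127.7, 8.18)},
        "right": {"volume": (2.95, 0.30), "t2": (119.5, 3.00)},
    },
    "right_hs": {
        "n": 18,
        "left": {"volume": (2.96, 0.28), "t2": (118.1, 4.49)},
        "right": {"volume": (2.20, 0.28), "t2": (128.1, 7.05)},
    },
    "bilateral_hs": {
        "n": 5,
        "left": {"volume": (2.07, 0.17), "t2": (126.8, 8.80)},
        "right": {"volume": (2.26, 0.29), "t2": (129.9, 4.91)},
    },
}

#: which groups count as pathologic for each side's classifier: a left
#: hippocampus is pathologic in left and bilateral HS, mirrored on the right
PATHOLOGIC_GROUPS = {
    "left": frozenset({"left_hs", "bilateral_hs"}),
    "right": frozenset({"right_hs", "bilateral_hs"}),
}


def control_stats(side: str, measure: str):
    """(mean, sd, n) of the control group for one side and measure."""
    grp = COHORT_GROUPS[CONTROL_GROUP]
    mean, sd = grp[side][measure]
    return mean, sd, grp["n"]
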