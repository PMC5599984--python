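"""Bland-Altman plotting for scan-rescan agreement."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stats import AgreementResult, paired_comparison

__all__ = ["bland_altman_plot"]


def bland_altman_plot(
    x, y, path: str | Path, result: AgreementResult | None = None,
    xlabel: str = "mean of repeats (msec)",
    ylabel: str = "difference (msec)",
) -> Path:
    """Scatter of pairwise differences against pair means, with the mean
    difference and 1.96-SD limits of agreement drawn as horizontal lines."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if result is None:
        result = paired_comparison(x, y)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((x + y) / 2.0, x - y, s=18, alpha=0.8)
    ax.axhline(result.mean_diff, color="k", lw=1)
    for lim in (result.loa_lower, result.loa_upper):
        ax.axhline(lim, color="k", lw=1, ls="--")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
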