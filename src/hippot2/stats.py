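"""Normative ranges, group comparisons, classification and agreement.

This module holds the cohort-level statistics of the pipeline:

* normative reference ranges, mean +/- 1.96 SD from healthy controls, per
  side or pooled bilaterally (the bilateral pool uses the exact two-sample
  moment-combination formula, not an average of SDs);
* two-tailed independent-samples t-tests assuming equal variances for group
  comparisons;
* binary logistic regression classifying each side's hippocampi into
  pathologic / nonpathologic from corrected volume and mean T2, singly or
  combined, fitted by iteratively reweighted least squares (IRLS) with
  perfect separation reported through a ``converged`` flag;
* Bland-Altman agreement (mean difference, SD of differences, limits of
  agreement) with a paired t-test, for scan-rescan reproducibility.

Sample SDs use the n-1 denominator throughout.  No multiple-testing
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import expit

__all__ = [
    "GroupStats",
    "ReferenceRange",
    "ClassifierModel",
    "AgreementResult",
    "pooled_bilateral_stats",
    "reference_range",
    "fit_logistic",
    "classify",
    "training_accuracy",
    "two_sample_t",
    "paired_comparison",
]

Z_REFERENCE = 1.96


@dataclass(frozen=True)
class GroupStats:
    """Mean, SD (n-1 denominator) and size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group must have n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def from_samples(cls, x) -> "GroupStats":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)), n=x.size)


@dataclass(frozen=True)
class ReferenceRange:
    """Normative interval center +/- 1.96 * SD."""

    lower: float
    upper: float
    center: float
    sd_pooled: float

    def flag(self, value: float) -> str:
        if value < self.lower:
            return "below"
        if value > self.upper:
            return "above"
        return "within"

    def rounded(self, ndigits: int) -> "ReferenceRange":
        return ReferenceRange(
            lower=round(self.lower, ndigits),
            upper=round(self.upper, ndigits),
            center=round(self.center, ndigits),
            sd_pooled=self.sd_pooled,
        )


def pooled_bilateral_stats(left: GroupStats, right: GroupStats) -> GroupStats:
    """Moments of the concatenation of both sides' samples.

    With equal n per side the pooled mean is the average of the side means
    and the Bessel-corrected pooled variance is

        [(n-1)(sL^2 + sR^2) + n((mL-m)^2 + (mR-m)^2)] / (2n - 1),

    identical to computing the SD of the concatenated raw samples.
    """
    if left.n != right.n:
        raise ValueError("bilateral pooling requires equal n per side")
    n = left.n
    mean = (left.mean + right.mean) / 2.0
    var = (
        (n - 1) * (left.sd**2 + right.sd**2)
        + n * ((left.mean - mean) ** 2 + (right.mean - mean) ** 2)
    ) / (2 * n - 1)
    return GroupStats(mean=mean, sd=float(np.sqrt(var)), n=2 * n)


def reference_range(stats: GroupStats, z: float = Z_REFERENCE) -> ReferenceRange:
    """Normative range mean +/- z*SD (z = 1.96, the central 95%)."""
    return ReferenceRange(
        lower=stats.mean - z * stats.sd,
        upper=stats.mean + z * stats.sd,
        center=stats.mean,
        sd_pooled=stats.sd,
    )


# ---------------------------------------------------------------------------
# logistic classification


@dataclass
class ClassifierModel:
    """Binary logistic model over (volume, T2) features.

    ``converged=False`` flags perfect separation or an iteration-cap stop;
    coefficients are still returned (at the last IRLS iterate).
    """

    intercept: float
    coefficients: np.ndarray
    feature_names: tuple[str, ...]
    converged: bool
    n_iter: int
    log_likelihood: float = float("nan")

    def _named(self, name: str) -> float:
        if name not in self.feature_names:
            raise AttributeError(f"model has no feature {name!r}")
        return float(self.coefficients[self.feature_names.index(name)])

    @property
    def coef_volume(self) -> float:
        return self._named("volume")

    @property
    def coef_t2(self) -> float:
        return self._named("t2")


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # stable sum y*eta - log(1+exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    features,
    labels,
    feature_names: tuple[str, ...] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ClassifierModel:
    """Maximum-likelihood logistic fit by IRLS.

    ``features`` is (n, k) with k = 1 or 2 (an intercept is always added);
    ``labels`` are 0/1 (1 = pathologic).  Convergence is declared when the
    largest coefficient change drops below ``tol``; on perfect separation
    the coefficients diverge, the iteration cap is hit and the model is
    returned with ``converged=False``.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 2:
        X = X.T
    y = np.asarray(labels, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("features and labels disagree in length")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("labels must be 0/1")
    if classes.size < 2 or min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise ValueError("need at least 2 examples per class")
    if feature_names is None:
        feature_names = ("volume", "t2")[: X.shape[1]] if X.shape[1] <= 2 else tuple(
            f"x{i}" for i in range(X.shape[1])
        )
    design = np.column_stack([np.ones(X.shape[0]), X])
    beta = np.zeros(design.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = design @ beta
        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        hessian = design.T @ (design * w[:, None])
        score = design.T @ (y - p)
        try:
            step = np.linalg.solve(hessian, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hessian, score, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = design @ beta
    return ClassifierModel(
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        feature_names=tuple(feature_names),
        converged=converged,
        n_iter=it,
        log_likelihood=_log_likelihood(eta, y),
    )


def classify(model: ClassifierModel, features):
    """Pathologic probability and 0.5-threshold decision per hippocampus."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.coefficients.size:
        X = X.reshape(-1, model.coefficients.size)
    eta = model.intercept + X @ model.coefficients
    prob = expit(eta)
    return prob, prob >= 0.5


def training_accuracy(model: ClassifierModel, features, labels) -> float:
    _, flags = classify(model, features)
    return float(np.mean(flags == (np.asarray(labels).ravel() == 1)))


# ---------------------------------------------------------------------------
# hypothesis tests and agreement


def two_sample_t(a, b):
    """Two-tailed independent-samples t-test assuming equal variances.

    Returns (t, p) with n_a + n_b - 2 degrees of freedom.  Degenerate input
    with zero pooled variance and equal means has no defined statistic and
    raises; zero variance with unequal means returns an infinite t, p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    pooled_var = (
        (a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var == 0:
        if np.mean(a) == np.mean(b):
            raise ValueError("zero pooled variance with equal means: t undefined")
        return float(np.sign(np.mean(a) - np.mean(b)) * np.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


@dataclass
class AgreementResult:
    """Bland-Altman summary of paired measurements (x - y differences)."""

    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    t_statistic: float
    p_value: float
    pearson_r: float
    n: int


def paired_comparison(x, y) -> AgreementResult:
    """Agreement between two repeats: Bland-Altman limits, paired t, Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    if sd_diff > 0:
        t, p = sps.ttest_rel(x, y)
    else:  # all differences identical; the paired t is degenerate
        t, p = (0.0, 1.0) if mean_diff == 0 else (float("inf"), 0.0)
    if np.std(x) > 0 and np.std(y) > 0:
        r = float(sps.pearsonr(x, y)[0])
    else:
        r = float("nan")
    return AgreementResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_lower=mean_diff - Z_REFERENCE * sd_diff,
        loa_upper=mean_diff + Z_REFERENCE * sd_diff,
        t_statistic=float(t),
        p_value=float(p),
        pearson_r=r,
        n=x.size,
    )
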