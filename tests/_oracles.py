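"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (per-voxel Python loops, generic
numerical optimisation) and shares no code path with the package.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def brute_force_resample(
    mask_voxels: np.ndarray,
    mask_affine: np.ndarray,
    world_to_world: np.ndarray,
    ref_shape: tuple[int, int, int],
    ref_affine: np.ndarray,
) -> np.ndarray:
    """Per-voxel pull-back: map each reference voxel centre to world space,
    through the inverse world transform, into the source grid, and take the
    nearest source voxel's label."""
    inv_world = np.linalg.inv(world_to_world)
    inv_src = np.linalg.inv(mask_affine)
    out = np.zeros(ref_shape, dtype=mask_voxels.dtype)
    for i in range(ref_shape[0]):
        for j in range(ref_shape[1]):
            for k in range(ref_shape[2]):
                world = ref_affine @ np.array([i, j, k, 1.0])
                src_world = inv_world @ world
                src_idx = inv_src @ src_world
                nearest = np.rint(src_idx[:3]).astype(int)
                if all(
                    0 <= nearest[a] < mask_voxels.shape[a] for a in range(3)
                ):
                    out[i, j, k] = mask_voxels[tuple(nearest)]
    return out


def brute_force_erode(binary: np.ndarray, element: np.ndarray) -> np.ndarray:
    """Per-voxel neighbourhood check: a voxel survives erosion iff every
    voxel under the (centred) structuring element is set."""
    offsets = [
        (a - 1, b - 1, c - 1)
        for a in range(3)
        for b in range(3)
        for c in range(3)
        if element[a, b, c]
    ]
    out = np.zeros_like(binary, dtype=bool)
    nx, ny, nz = binary.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not binary[i, j, k]:
                    continue
                keep = True
                for di, dj, dk in offsets:
                    ii, jj, kk = i + di, j + dj, k + dk
                    if not (0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz):
                        keep = False
                        break
                    if not binary[ii, jj, kk]:
                        keep = False
                        break
                if keep:
                    out[i, j, k] = True
    return out


def t2_through_two_points(s1, s2, te1, te2, bracket=(1.0, 10000.0)):
    """Solve A*exp(-te/T2) through both (TE, S) points with a root finder:
    eliminate A and find the root of S1*exp(-(te2-te1)/T2) - S2... written
    directly as g(T2) = ln(S1/S2) - (te2-te1)/T2."""

    def g(t2):
        return np.log(s1 / s2) - (te2 - te1) / t2

    return optimize.brentq(g, *bracket, xtol=1e-12, rtol=1e-14)


def maximize_logistic_likelihood(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Gradient-based maximiser of the logistic log-likelihood (BFGS),
    independent of the IRLS path.  Returns [intercept, coefficients...]."""
    design = np.column_stack([np.ones(len(y)), X])

    def neg_ll(beta):
        eta = design @ beta
        return -np.sum(y * eta - np.logaddexp(0.0, eta))

    def grad(beta):
        eta = design @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        return -design.T @ (y - p)

    res = optimize.minimize(
        neg_ll,
        np.zeros(design.shape[1]),
        jac=grad,
        method="BFGS",
        options={"gtol": 1e-12, "maxiter": 2000},
    )
    return res.x


def misclassification_loss(gm, csf, cutoff) -> float:
    return float(np.mean(gm > cutoff) + np.mean(csf < cutoff))


def best_midpoint_cutoff(gm, csf):
    """Exhaustive search over midpoints of adjacent order statistics of the
    pooled sample."""
    pooled = np.sort(np.concatenate([gm, csf]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    losses = [misclassification_loss(gm, csf, c) for c in mids]
    best = int(np.argmin(losses))
    return float(mids[best]), float(losses[best])
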