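"""Straight-line per-voxel reference implementation of the highCV
extraction, used as an independent oracle for the vectorized pipeline.

Everything here is deliberately naive: explicit Python loops, manual
percentile/quantile interpolation, no shared code with the package.
"""

import math

import numpy as np


def ref_percentile(values, pct):
    """Linear-interpolation percentile of a list (pct in [0, 100])."""
    v = sorted(float(x) for x in values)
    n = len(v)
    if n == 1:
        return v[0]
    h = (n - 1) * pct / 100.0
    lo = int(math.floor(h))
    hi = min(lo + 1, n - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def ref_temporal_stats(data4d, brain):
    """Per-voxel population sigma and mean, zero outside the brain."""
    nx, ny, nz, nt = data4d.shape
    sigma = np.zeros((nx, ny, nz))
    mu = np.zeros((nx, ny, nz))
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not brain[i, j, k]:
                    continue
                vals = [float(data4d[i, j, k, t]) for t in range(nt)]
                m = sum(vals) / nt
                var = sum((v - m) ** 2 for v in vals) / nt
                mu[i, j, k] = m
                sigma[i, j, k] = math.sqrt(var)
    return sigma, mu


def ref_cv(sigma, mu):
    pos = [mu[i] for i in np.ndindex(mu.shape) if mu[i] > 0]
    eps = 1e-6 * ref_percentile(pos, 50.0) if pos else 0.0
    cv = np.zeros_like(mu)
    for idx in np.ndindex(mu.shape):
        if mu[idx] > eps:
            cv[idx] = sigma[idx] / mu[idx]
    return cv


def ref_highcv_pipeline(data4d, brain, ventricles, strip_fraction=0.05):
    """Full highCV extraction, loop-based.

    Returns a dict with every intermediate so each stage can be compared.
    """
    sigma, mu = ref_temporal_stats(data4d, brain)
    cv = ref_cv(sigma, mu)
    in_mask = [cv[idx] for idx in np.ndindex(cv.shape) if brain[idx] and cv[idx] > 0]
    rmin = ref_percentile(in_mask, 2.0)
    rmax = ref_percentile(in_mask, 98.0)
    thr = rmin + 0.5 * (rmax - rmin)
    high = np.zeros(brain.shape, dtype=bool)
    for idx in np.ndindex(cv.shape):
        if brain[idx] and cv[idx] >= thr:
            high[idx] = True
    # ventricle exclusion
    for idx in np.ndindex(cv.shape):
        if ventricles[idx]:
            high[idx] = False
    # bolus peak: minimum of the in-brain mean time course
    nt = data4d.shape[3]
    course = []
    brain_idx = [idx for idx in np.ndindex(brain.shape) if brain[idx]]
    for t in range(nt):
        course.append(sum(float(data4d[idx][t]) for idx in brain_idx) / len(brain_idx))
    t_star = min(range(nt), key=lambda t: (course[t], t))
    # low-intensity strip at t_star over the highCV voxels
    high_idx = [idx for idx in np.ndindex(high.shape) if high[idx]]
    if high_idx and strip_fraction > 0:
        intensities = [float(data4d[idx][t_star]) for idx in high_idx]
        q = ref_percentile(intensities, strip_fraction * 100.0)
        for idx in high_idx:
            if data4d[idx][t_star] < q:
                high[idx] = False
    return {
        "sigma": sigma, "mu": mu, "cv": cv, "rmin": rmin, "rmax": rmax,
        "threshold": thr, "t_star": t_star, "highcv": high,
    }


def ref_cvi(high, lepto, axis_len_x, voxel_volume, affected="left"):
    """Hemisphere volumes and CVI by explicit counting (left = low x)."""
    mid_lo = axis_len_x // 2
    mid_hi = (axis_len_x + 1) // 2
    n_left = n_right = 0
    for idx in np.ndindex(high.shape):
        if high[idx] and lepto[idx]:
            if idx[0] < mid_lo:
                n_left += 1
            elif idx[0] >= mid_hi:
                n_right += 1
    aff, unaff = (n_left, n_right) if affected == "left" else (n_right, n_left)
    return aff * voxel_volume, unaff * voxel_volume
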