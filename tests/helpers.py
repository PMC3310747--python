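"""Independent brute-force oracles used to cross-check the implementation.

These deliberately recompute results the slow, obvious way (per-peak
per-window membership scans, full pairwise ranking matrices, explicit
Gaussian densities) and share no code with the package's filtering or
classification paths.
"""

import numpy as np
from scipy.stats import multivariate_normal


def brute_force_removal(mz, windows):
    """Boolean keep-mask: peak survives unless strictly inside a window."""
    keep = []
    for m in mz:
        inside = False
        for w in windows:
            if w.lo < m < w.hi:
                inside = True
        keep.append(not inside)
    return np.array(keep, dtype=bool)


def brute_force_window_rank(mz, intensity, half_width, h):
    """O(n^2) sliding-window ranking: peak i is kept iff fewer than h peaks
    within [mz_i - hw, mz_i + hw] outrank it (higher intensity, or equal
    intensity at lower m/z)."""
    mz = np.asarray(mz)
    intensity = np.asarray(intensity)
    d = np.abs(mz[None, :] - mz[:, None]) <= half_width
    better = d & ((intensity[None, :] > intensity[:, None])
                  | ((intensity[None, :] == intensity[:, None])
                     & (mz[None, :] < mz[:, None])))
    return better.sum(axis=1) < h


def brute_force_deisotope(mz, intensity, tol=0.2):
    """Cluster walk in descending intensity order, removing peaks 1 or 2 Da
    above a more intense still-retained peak."""
    order = sorted(range(len(mz)), key=lambda i: (-intensity[i], mz[i]))
    keep = [True] * len(mz)
    for i in order:
        if not keep[i]:
            continue
        for j in range(len(mz)):
            if not keep[j] or intensity[j] >= intensity[i]:
                continue
            delta = mz[j] - mz[i]
            if abs(delta - 1.0) <= tol or abs(delta - 2.0) <= tol:
                keep[j] = False
    return np.array(keep, dtype=bool)


def bayes_posterior(x, means, cov, priors):
    """Explicit Gaussian Bayes posterior: pi_k N(x; mu_k, Sigma) normalised."""
    dens = np.array([p * multivariate_normal.pdf(x, mean=m, cov=cov)
                     for m, p in zip(means, priors)])
    return dens / dens.sum()
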