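"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive explicit-loop or exhaustive-enumeration
implementations so they stay independent of the vectorised production code
they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def adaptive_mask_oracle(gray, region_size, gain_mu=1.1, gain_sigma=0.3):
    """Sliding-window local threshold by explicit loops (no resizing).

    Negates the image, pads symmetrically (window extends one pixel further
    toward lower indices for even sizes) and thresholds each pixel at
    ``gain_mu * mu - gain_sigma * sigma`` of its window.
    """
    neg = 1.0 - np.asarray(gray, dtype=np.float64)
    h, w = neg.shape
    lo = region_size // 2
    hi = region_size - lo - 1
    padded = np.pad(neg, ((lo, hi), (lo, hi)), mode="symmetric")
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            win = padded[i : i + region_size, j : j + region_size]
            mu = win.mean()
            sigma = win.std()
            out[i, j] = neg[i, j] > gain_mu * mu - gain_sigma * sigma
    return out


def otsu_oracle(values, nbins=256):
    """Exhaustive search over all bin-edge thresholds maximising between-class
    variance computed from the raw pixel values."""
    vals = np.asarray(values, dtype=np.float64).ravel()
    edges = np.linspace(0.0, 1.0, nbins + 1)
    best, best_thr = -np.inf, None
    for t in range(nbins - 1):
        thr = edges[t + 1]
        c0 = vals[vals < thr]
        c1 = vals[vals >= thr]
        if c0.size == 0 or c1.size == 0:
            continue
        between = c0.size * c1.size * (c0.mean() - c1.mean()) ** 2
        if between > best:
            best, best_thr = between, thr
    return best_thr


def wilcoxon_signflip_oracle(a, b, alternative="two-sided"):
    """Exact signed-rank p-value by enumerating all 2**n sign assignments."""
    from scipy.stats import rankdata

    d = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    # signs pick which ranks count as "positive"
    w_all = np.array(
        [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=n)
        ]
    )
    total = w_all.size
    if alternative == "greater":
        return np.sum(w_all >= w_obs - 1e-9) / total
    if alternative == "less":
        return np.sum(w_all <= w_obs + 1e-9) / total
    p_lo = np.sum(w_all <= w_obs + 1e-9) / total
    p_hi = np.sum(w_all >= w_obs - 1e-9) / total
    return min(1.0, 2.0 * min(p_lo, p_hi))


def friedman_permutation_oracle(data):
    """Exact Friedman permutation p by brute-force enumeration of all
    within-block orderings (feasible for small cohorts)."""
    arr = np.asarray(data, dtype=np.float64)
    n, k = arr.shape
    from scipy.stats import rankdata

    ranks = np.vstack([rankdata(row) for row in arr])
    perms = np.array(list(itertools.permutations(range(k))))
    combos = ranks[0][perms]  # (k!, k)
    for row in ranks[1:]:
        combos = (combos[:, None, :] + row[perms][None, :, :]).reshape(-1, k)
    ss = ((combos - combos.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    obs = float(((ranks.sum(axis=0) - ranks.sum() / k) ** 2).sum())
    return float(np.mean(ss >= obs - 1e-9))
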