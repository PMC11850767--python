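"""Lagged cross-correlation of daily neural and behavioral series.

Cross-covariance uses the 1/T normalization (T = series length); the
correlation divides by the product of the two series' SDs, so r(0) = 1 on
identical series and |r(k)| shrinks toward 0 at large lags.  Significance
comes from a permutation test on the maximum-|r| statistic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cross_correlation", "optimal_lag", "permutation_test"]


def cross_correlation(y1: np.ndarray, y2: np.ndarray,
                      max_lag: int | None = None):
    """r(k) for k = 0, ±1, ±2, … ±max_lag (default ⌊T/2⌋).

    r(k) correlates y1 at time t with y2 at time t+k:
    c(k) = (1/T) Σ_t (y1_t − ȳ1)(y2_{t+k} − ȳ2), r(k) = c(k)/(e1 e2).
    Returns (lags, r).
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if len(y1) != len(y2):
        raise ValueError("series must have equal length")
    T = len(y1)
    if T < 3:
        raise ValueError("need at least 3 points")
    e1, e2 = np.std(y1), np.std(y2)
    if e1 == 0 or e2 == 0:
        raise ValueError("zero-variance series")
    if max_lag is None:
        max_lag = T // 2
    d1 = y1 - y1.mean()
    d2 = y2 - y2.mean()
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.empty(len(lags))
    for i, k in enumerate(lags):
        if k >= 0:
            c = np.sum(d1[: T - k] * d2[k:]) / T
        else:
            c = np.sum(d1[-k:] * d2[: T + k]) / T
        r[i] = c / (e1 * e2)
    return lags, r


def optimal_lag(lags: np.ndarray, r: np.ndarray) -> int:
    """Lag with the greatest (signed) cross-correlation; ties prefer the
    smallest |k|, then the negative lag."""
    r = np.asarray(r, dtype=float)
    best = r.max()
    cand = lags[np.isclose(r, best)]
    cand = sorted(cand, key=lambda k: (abs(k), k))
    return int(cand[0])


def permutation_test(y1: np.ndarray, y2: np.ndarray, n: int = 1000,
                     seed: int = 0, max_lag: int | None = None) -> float:
    """Permutation p-value for the max-|r| statistic: one series is permuted
    independently n times; p = (1 + #{null ≥ observed}) / (n + 1)."""
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    rng = np.random.default_rng(seed)
    _, r_obs = cross_correlation(y1, y2, max_lag)
    obs = np.max(np.abs(r_obs))
    T = len(y1)
    if max_lag is None:
        max_lag = T // 2
    # vectorized null: permute y2, recompute max |r| over lags
    d1 = y1 - y1.mean()
    e1 = np.std(y1)
    count = 0
    perms = np.stack([rng.permutation(y2) for _ in range(n)])
    d2 = perms - perms.mean(axis=1, keepdims=True)
    e2 = perms.std(axis=1)
    for k in range(-max_lag, max_lag + 1):
        if k >= 0:
            c = d2[:, k:] @ d1[: T - k] / T
        else:
            c = d2[:, : T + k] @ d1[-k:] / T
        r_null_k = np.abs(c / (e1 * e2))
        if k == -max_lag:
            best = r_null_k
        else:
            best = np.maximum(best, r_null_k)
    count = int(np.sum(best >= obs - 1e-12))
    return (1 + count) / (n + 1)
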