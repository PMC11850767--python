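"""Peri-event firing-rate analysis of single units.

Responsiveness is decided by a Wilcoxon signed-rank test on paired
baseline/response firing rates (3 s windows) together with a z-score rule:
mean response-window z strictly above 1.5 or at/below −1.  Responsive units
are grouped into functional clusters by hierarchical clustering of their
event-aligned z-score series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import gaussian_filter1d
from scipy.stats import gaussian_kde, ks_2samp, ranksums, wilcoxon

__all__ = [
    "ResponseProfile",
    "bin_spikes",
    "peri_event_z",
    "cluster_units",
    "response_magnitude_compare",
    "rate_variance_distribution",
    "cluster_realignment",
    "MIN_RATE_HZ",
]

MIN_RATE_HZ = 0.1  # units below this mean rate are excluded


@dataclass
class ResponseProfile:
    unit: int
    event_type: str
    z_series: np.ndarray           # event-aligned mean z-score series
    mean_z: float
    p_value: float
    responsive: bool
    excluded: bool = False
    exclusion_reason: str | None = None


def bin_spikes(spike_times: np.ndarray, t_start: float, t_end: float,
               bin_s: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Histogram spike times into firing rates (Hz) on a regular grid."""
    edges = np.arange(t_start, t_end + bin_s, bin_s)
    counts, _ = np.histogram(spike_times, bins=edges)
    return counts / bin_s, edges[:-1]


def peri_event_z(
    spike_times: np.ndarray,
    event_times: np.ndarray,
    event_type: str = "snatch",
    unit: int = 0,
    session_length: float | None = None,
    bin_s: float = 0.05,
    smooth_sd_s: float = 0.1,
    baseline_window: tuple[float, float] = (-4.0, -1.0),
    response_window_s: float = 3.0,
) -> ResponseProfile:
    """Peri-event responsiveness of one unit.

    Rates in 50 ms bins are Gaussian-smoothed (SD 100 ms) before z-scoring
    against the per-event baseline (default: the 3 s ending 1 s before
    onset).  A signed-rank test compares baseline vs response mean rates
    across events.  Units below 0.1 Hz overall, or with zero baseline SD,
    are excluded.
    """
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    event_times = np.asarray(event_times, dtype=float)
    if len(event_times) < 5:
        raise ValueError("need at least 5 events for the paired test")
    if session_length is None:
        session_length = spike_times[-1] if len(spike_times) else 1.0
    mean_rate = len(spike_times) / session_length
    if mean_rate < MIN_RATE_HZ:
        return ResponseProfile(unit, event_type, np.array([]), np.nan, np.nan,
                               False, excluded=True,
                               exclusion_reason="mean rate below 0.1 Hz")

    pre, post = baseline_window[0], response_window_s
    n_bins = int(round((post - pre) / bin_s))
    aligned = np.empty((len(event_times), n_bins))
    for i, ev in enumerate(event_times):
        rates, _ = bin_spikes(spike_times, ev + pre, ev + post, bin_s)
        aligned[i] = gaussian_filter1d(rates[:n_bins], smooth_sd_s / bin_s)

    base_sl = slice(0, int(round((baseline_window[1] - baseline_window[0]) / bin_s)))
    resp_sl = slice(int(round(-pre / bin_s)), n_bins)
    base_rates = aligned[:, base_sl].mean(axis=1)
    resp_rates = aligned[:, resp_sl].mean(axis=1)

    base_mu = aligned[:, base_sl].mean()
    base_sd = aligned[:, base_sl].std()
    if base_sd == 0:
        return ResponseProfile(unit, event_type, np.array([]), np.nan, np.nan,
                               False, excluded=True,
                               exclusion_reason="zero baseline SD")
    z_series = (aligned.mean(axis=0) - base_mu) / base_sd
    mean_z = float(z_series[resp_sl].mean())

    diffs = resp_rates - base_rates
    if np.allclose(diffs, 0):
        p = 1.0
    else:
        _, p = wilcoxon(base_rates, resp_rates, zero_method="wilcox")
    responsive = bool(p < 0.05 and (mean_z > 1.5 or mean_z <= -1.0))
    return ResponseProfile(unit, event_type, z_series, mean_z, float(p),
                           responsive)


def cluster_units(
    response_matrix: np.ndarray,
    responsive_mask: np.ndarray | None = None,
    cut: float = 0.4,
    cut_mode: str = "fraction",
) -> np.ndarray:
    """Functional clusters from event-aligned z-series (rows = units).

    Euclidean distance, average linkage; dendrogram cut at ``cut`` times the
    maximum linkage height (``cut_mode='fraction'``, default) or at absolute
    height (``cut_mode='absolute'``).  Non-responsive units get label 0 (a
    residual cluster); clustered units get labels 1..n.
    """
    X = np.asarray(response_matrix, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 units")
    if responsive_mask is None:
        responsive_mask = np.ones(len(X), dtype=bool)
    labels = np.zeros(len(X), dtype=int)
    idx = np.where(responsive_mask)[0]
    if len(idx) >= 2:
        Z = linkage(X[idx], method="average", metric="euclidean")
        height = cut * Z[:, 2].max() if cut_mode == "fraction" else cut
        labels[idx] = fcluster(Z, t=height, criterion="distance")
    elif len(idx) == 1:
        labels[idx] = 1
    return labels


def response_magnitude_compare(group_a: np.ndarray, group_b: np.ndarray):
    """Two-sided Wilcoxon rank-sum on mean response-window z between groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    stat, p = ranksums(a, b)
    return {"statistic": float(stat), "p_value": float(p)}


def rate_variance_distribution(group_a_rates: np.ndarray,
                               group_b_rates: np.ndarray,
                               grid: np.ndarray | None = None):
    """Per-unit session rate variances compared across groups: Gaussian-kernel
    density estimates plus a two-sample Kolmogorov–Smirnov test."""
    var_a = np.var(np.asarray(group_a_rates, float), axis=1)
    var_b = np.var(np.asarray(group_b_rates, float), axis=1)
    if len(var_a) < 2 or len(var_b) < 2:
        raise ValueError("need at least 2 units per group")
    if grid is None:
        hi = max(var_a.max(), var_b.max())
        grid = np.linspace(0, hi * 1.2 + 1e-9, 200)
    out = {"variances_a": var_a, "variances_b": var_b, "grid": grid}
    for key, v in (("density_a", var_a), ("density_b", var_b)):
        out[key] = gaussian_kde(v)(grid) if np.std(v) > 0 else None
    D, p = ks_2samp(var_a, var_b)
    out["ks_D"] = float(D)
    out["ks_p"] = float(p)
    return out


def cluster_realignment(day0_labels: dict[int, int], dayn_labels: dict[int, int],
                        identity_map: dict[int, int]) -> pd.DataFrame:
    """Cluster-to-cluster percentage matrix for units tracked across days.

    ``identity_map`` maps day-0 unit id → day-N unit id.  Rows (day-0
    clusters) sum to 100%.
    """
    if not identity_map:
        raise ValueError("empty identity map")
    pairs = [(day0_labels[u0], dayn_labels[un])
             for u0, un in identity_map.items()
             if u0 in day0_labels and un in dayn_labels]
    if not pairs:
        raise ValueError("no tracked units with labels on both days")
    c0 = sorted({p[0] for p in pairs})
    cn = sorted({p[1] for p in pairs})
    mat = pd.DataFrame(0.0, index=c0, columns=cn)
    for a, b in pairs:
        mat.loc[a, b] += 1
    return mat.div(mat.sum(axis=1), axis=0) * 100.0
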