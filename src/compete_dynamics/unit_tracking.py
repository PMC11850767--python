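"""Cross-day unit identity matching.

A unit recorded on two days is accepted as the same neuron when both hold:

* waveform similarity w — the maximum Pearson correlation between
  time-shifted average waveforms — exceeds 0.81, and
* the log ISIH score I' = ln I is below 1, where
  I(A, B) = sqrt(Σ_i (A_i − B_i)² / σ_i²) compares the eight parameters of
  three-component log-normal inter-spike-interval mixtures.

The σ_i normalizers default to the across-population SD of each fitted
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

__all__ = [
    "ISIHParams",
    "MatchScore",
    "waveform_similarity",
    "fit_isih",
    "isih_score",
    "decide_same_unit",
    "match_units",
    "W_THRESHOLD",
    "I_PRIME_THRESHOLD",
]

W_THRESHOLD = 0.81
I_PRIME_THRESHOLD = 1.0
_LOG_GUARD = 1e-12


@dataclass
class ISIHParams:
    """Three-component log-normal mixture: log-means μ1..μ3 (ascending),
    log-SDs σ1..σ3, mixing weights π1, π2 (π3 implied)."""

    mu: np.ndarray
    sigma: np.ndarray
    pi: np.ndarray          # first two mixing probabilities

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.mu.shape != (3,) or self.sigma.shape != (3,) or self.pi.shape != (2,):
            raise ValueError("expect 3 means, 3 SDs, 2 mixing probs")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        if not (0.0 <= self.pi.sum() <= 1.0 + 1e-9):
            raise ValueError("mixing probabilities must lie in the simplex")

    @property
    def vector(self) -> np.ndarray:
        """The eight free parameters in fixed order (μ1..μ3, σ1..σ3, π1, π2)."""
        return np.concatenate([self.mu, self.sigma, self.pi])


@dataclass
class MatchScore:
    w: float
    I: float
    I_prime: float
    same_unit: bool


def waveform_similarity(wf_a: np.ndarray, wf_b: np.ndarray,
                        max_shift: int | None = None) -> float:
    """Maximum Pearson correlation over integer time shifts.

    Scale-invariant; requires ≥ 50% overlap at the maximum shift.  Raises on
    constant (zero-variance) waveforms.
    """
    a = np.asarray(wf_a, dtype=float)
    b = np.asarray(wf_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("waveforms must have equal length (same sampling)")
    n = len(a)
    if max_shift is None:
        max_shift = n // 4
    if n - max_shift < n / 2:
        raise ValueError("max_shift leaves less than 50% overlap")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant waveform has undefined correlation")
    best = -1.0
    for s in range(-max_shift, max_shift + 1):
        if s >= 0:
            seg_a, seg_b = a[s:], b[:n - s]
        else:
            seg_a, seg_b = a[:n + s], b[-s:]
        if np.std(seg_a) == 0 or np.std(seg_b) == 0:
            continue
        r = np.corrcoef(seg_a, seg_b)[0, 1]
        best = max(best, r)
    return float(best)


def fit_isih(isis: np.ndarray, seed: int = 0) -> ISIHParams:
    """Maximum-likelihood three-component log-normal mixture via EM on
    log-ISIs (k-means init, 10 restarts, fixed seed).  Components are
    reordered by ascending log-mean for identifiability."""
    isis = np.asarray(isis, dtype=float)
    if np.any(isis <= 0):
        raise ValueError("inter-spike intervals must be positive")
    if len(isis) < 50:
        raise ValueError("need at least 50 ISIs")
    log_isis = np.log(isis)[:, None]
    gm = GaussianMixture(
        n_components=3, covariance_type="diag", n_init=10,
        init_params="k-means++", random_state=seed, tol=1e-8, max_iter=500,
        reg_covar=1e-10,
    ).fit(log_isis)
    mu = gm.means_.ravel()
    sigma = np.sqrt(gm.covariances_.ravel())
    pi = gm.weights_.ravel()
    order = np.argsort(mu)
    return ISIHParams(mu=mu[order], sigma=sigma[order], pi=pi[order][:2])


def isih_score(a: ISIHParams, b: ISIHParams,
               norm_sd: np.ndarray) -> tuple[float, float]:
    """ISIH distance I = sqrt(Σ (A_i − B_i)²/σ_i²) over the eight ordered
    parameters, and its natural log I' (log of zero guarded at 1e-12)."""
    norm_sd = np.asarray(norm_sd, dtype=float)
    if norm_sd.shape != (8,):
        raise ValueError("norm_sd must have 8 entries matching the parameter order")
    if np.any(norm_sd <= 0):
        raise ValueError("norm_sd must be positive")
    diff = a.vector - b.vector
    I = float(np.sqrt(np.sum((diff / norm_sd) ** 2)))
    I_prime = float(np.log(max(I, _LOG_GUARD)))
    return I, I_prime


def decide_same_unit(w: float, I_prime: float) -> bool:
    """Conjunction of the two thresholds: w strictly above 0.81 and I'
    strictly below 1."""
    return bool(w > W_THRESHOLD and I_prime < I_PRIME_THRESHOLD)


def population_norm_sd(params_list: list[ISIHParams]) -> np.ndarray:
    """Across-population SD of each of the eight ISIH parameters (the default
    σ_i normalizers of the ISIH score)."""
    mat = np.stack([p.vector for p in params_list])
    sd = mat.std(axis=0)
    return np.maximum(sd, 1e-6)


def match_units(day0: list[dict], day1: list[dict],
                norm_sd: np.ndarray | None = None,
                max_shift: int | None = None, seed: int = 0):
    """Score all day-0 × day-1 unit pairs and decide matches.

    ``day0``/``day1`` entries need 'unit', 'waveform' and either
    'isih_params' (8-vector) or raw 'isis'.  Returns a DataFrame with one
    row per pair.
    """
    import pandas as pd

    def get_params(rec) -> ISIHParams:
        if "isih_params" in rec and rec["isih_params"] is not None:
            v = np.asarray(rec["isih_params"], dtype=float)
            return ISIHParams(mu=v[:3], sigma=v[3:6], pi=v[6:8])
        return fit_isih(rec["isis"], seed=seed)

    p0 = [get_params(r) for r in day0]
    p1 = [get_params(r) for r in day1]
    if norm_sd is None:
        norm_sd = population_norm_sd(p0 + p1)
    rows = []
    for i, r0 in enumerate(day0):
        for j, r1 in enumerate(day1):
            w = waveform_similarity(r0["waveform"], r1["waveform"], max_shift)
            I, I_p = isih_score(p0[i], p1[j], norm_sd)
            rows.append({
                "unit_day0": r0["unit"], "unit_day1": r1["unit"],
                "w": w, "I": I, "I_prime": I_p,
                "same_unit": decide_same_unit(w, I_p),
            })
    return pd.DataFrame(rows)
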