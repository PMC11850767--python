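"""Metrics computed from a fitted switching linear dynamical system.

Covers the post-fit analysis chain: emission-aware PCA of the latent space,
per-state flow fields and dynamic velocities, rotation angles about the
trajectory's geometric median referenced to the state-1 point attractor,
empirical transition/dwell statistics, attractor time-constant scores and a
sequentiality index with shuffle nulls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Pca2D",
    "pca_transform",
    "flow_field",
    "dynamic_velocity",
    "point_attractor",
    "geometric_median",
    "rotation_angle",
    "angle_behavior_ecdf",
    "transition_stats",
    "quartile_levels",
    "attractor_scores",
    "sequentiality_index",
]


@dataclass
class Pca2D:
    """Whitening + SVD change of basis that orders latent dimensions by the
    variance they contribute to the observations."""

    W_white: np.ndarray          # (D, D) whitening matrix
    P: np.ndarray                # (D, D) = S V^T from SVD of C W^{-1}
    x2: np.ndarray               # (T, D) transformed latents x'' = P W x
    var_frac: np.ndarray         # per-component variance fractions, descending

    def transform_points(self, x: np.ndarray) -> np.ndarray:
        return (self.P @ self.W_white @ np.asarray(x, float).T).T

    def transform_dynamics(self, A: np.ndarray, b: np.ndarray):
        """Express x_{t+1} = A x_t + b in the transformed coordinates."""
        M = self.P @ self.W_white
        Minv = np.linalg.inv(M)
        return M @ A @ Minv, M @ b


def pca_transform(fit_result) -> Pca2D:
    """Whiten the latents, rotate by the SVD of the transformed emission
    matrix, and return latents ordered by emitted variance.

    Steps: whitening W with cov(W x) = I; C' = C W^{-1}; SVD C' = U S V^T;
    P = S V^T; x'' = P W x.  The emission then reads y = U x'' with U
    orthonormal, so cov(x'') = S² is diagonal with descending entries: the
    first two components carry the most observed variance.
    """
    if fit_result.params.emission_kind != "gaussian":
        raise ValueError("PCA transform requires Gaussian emissions")
    x = fit_result.x
    C = fit_result.params.C[0]
    cov = np.cov(x.T)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, 1e-12)
    W_white = evecs @ np.diag(evals**-0.5) @ evecs.T
    C_prime = C @ np.linalg.inv(W_white)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        import warnings

        warnings.warn("rank-deficient emission matrix; using pseudo-inverse",
                      RuntimeWarning, stacklevel=2)
    U, s, Vt = np.linalg.svd(C_prime, full_matrices=False)
    P = np.diag(s) @ Vt
    x2 = (P @ W_white @ x.T).T
    var = x2.var(axis=0)
    var_frac = var / var.sum() if var.sum() > 0 else var
    return Pca2D(W_white=W_white, P=P, x2=x2, var_frac=var_frac)


def flow_field(params, pca: Pca2D, grid: np.ndarray, state: int) -> np.ndarray:
    """Displacement vectors of one state's dynamics map at 2D grid points,
    expressed in the first two transformed coordinates.

    ``grid`` is (G, 2); off-plane coordinates are held at zero.
    """
    D = params.D
    A2, b2 = pca.transform_dynamics(params.A[state], params.b[state])
    pts = np.zeros((len(grid), D))
    pts[:, :2] = grid
    nxt = pts @ A2.T + b2
    return (nxt - pts)[:, :2]


def dynamic_velocity(params, x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-state mean ‖A_z x_t‖ over that state's visited bins, normalized to
    state 1 (index 0).  Unvisited states yield NaN."""
    K = params.K
    raw = np.full(K, np.nan)
    for k in range(K):
        mask = z == k
        if mask.any():
            raw[k] = np.mean(np.linalg.norm(x[mask] @ params.A[k].T, axis=1))
    if not np.isfinite(raw[0]):
        raise ValueError("state 1 never visited; cannot normalize")
    return raw / raw[0]


def dynamic_velocity_raw(params, x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Un-normalized per-state mean ‖A_z x_t‖ (NaN for unvisited states)."""
    K = params.K
    raw = np.full(K, np.nan)
    for k in range(K):
        mask = z == k
        if mask.any():
            raw[k] = np.mean(np.linalg.norm(x[mask] @ params.A[k].T, axis=1))
    return raw


def point_attractor(x: np.ndarray, z: np.ndarray, A1: np.ndarray,
                    pca: Pca2D | None = None) -> np.ndarray:
    """The visited state-1 bin minimizing ‖A₁ x_t‖ (ties → earliest bin),
    optionally projected to the transformed plane."""
    mask = z == 0
    if not mask.any():
        raise ValueError("state 1 never visited")
    pts = x[mask]
    norms = np.linalg.norm(pts @ np.asarray(A1, float).T, axis=1)
    best = pts[int(np.argmin(norms))]
    if pca is not None:
        return pca.transform_points(best[None, :])[0, :2]
    return best


def geometric_median(points: np.ndarray, tol: float = 1e-8,
                     max_iter: int = 1000) -> np.ndarray:
    """Weiszfeld iteration for the L1 spatial median, with the standard guard
    when an iterate coincides with a data point."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) == 1:
        return pts[0].copy()
    m = pts.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(pts - m, axis=1)
        hit = d < 1e-12
        if hit.any():
            # check whether the coincident data point is the minimizer
            others = pts[~hit]
            if len(others) == 0:
                return m
            r = np.sum((others - m) / np.linalg.norm(others - m, axis=1)[:, None],
                       axis=0)
            if np.linalg.norm(r) <= hit.sum():
                return m
            m_new = m + r / np.linalg.norm(r) * 1e-8
        else:
            w = 1.0 / d
            m_new = (pts * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(m_new - m) < tol:
            return m_new
        m = m_new
    return m


def _global_rotation_sign(v: np.ndarray) -> float:
    """Sign of the mean signed angular increment of the centered trajectory."""
    ang = np.arctan2(v[:, 1], v[:, 0])
    d = np.diff(ang)
    d = (d + np.pi) % (2 * np.pi) - np.pi
    return 1.0 if d.mean() >= 0 else -1.0


def rotation_angle(
    traj: np.ndarray,
    attractor: np.ndarray,
    median: np.ndarray,
    rotation_direction: float | None = None,
) -> np.ndarray:
    """Angle series θ_t ∈ [0°, 360°) of the trajectory about the geometric
    median, measured from the direction of the state-1 point attractor.

    θ = arccos(u·v / ‖u‖‖v‖) with u = attractor − median and
    v = x_t − median; the 2D cross product u_x v_y − u_y v_x decides whether
    θ or 360° − θ is reported, so that angles accumulate along the
    trajectory's own rotation direction.  Bins at the median are NaN.
    """
    traj = np.asarray(traj, dtype=float)[:, :2]
    u = np.asarray(attractor, dtype=float)[:2] - np.asarray(median, dtype=float)[:2]
    if np.linalg.norm(u) < 1e-12:
        raise ValueError("attractor coincides with the geometric median")
    v = traj - np.asarray(median, dtype=float)[:2]
    nv = np.linalg.norm(v, axis=1)
    if rotation_direction is None:
        rotation_direction = _global_rotation_sign(v)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(v @ u / (np.linalg.norm(u) * nv), -1.0, 1.0)
    theta = np.degrees(np.arccos(cosang))
    cross = u[0] * v[:, 1] - u[1] * v[:, 0]
    # cross > 0: v lies counterclockwise of u
    ccw_of_u = cross > 0
    if rotation_direction > 0:
        theta = np.where(ccw_of_u, theta, 360.0 - theta)
    else:
        theta = np.where(~ccw_of_u, theta, 360.0 - theta)
    theta = np.where(nv < 1e-12, np.nan, theta % 360.0)
    return theta


def angle_behavior_ecdf(theta: np.ndarray, labels: np.ndarray):
    """Per-class empirical CDF of the rotation angle and its 50% point
    (smallest angle with ECDF ≥ 0.5)."""
    theta = np.asarray(theta, dtype=float)
    labels = np.asarray(labels)
    out = {}
    for cls in np.unique(labels):
        vals = np.sort(theta[(labels == cls) & np.isfinite(theta)])
        if len(vals) == 0:
            continue
        ecdf_x = vals
        ecdf_y = np.arange(1, len(vals) + 1) / len(vals)
        p50 = float(vals[int(np.searchsorted(ecdf_y, 0.5))])
        out[str(cls)] = {"x": ecdf_x, "y": ecdf_y, "p50": p50}
    return out


def transition_stats(z: np.ndarray, trial_edges: np.ndarray | None = None):
    """Empirical transition matrix, self-transition probabilities and dwell
    times from a discrete-state series.

    ``trial_edges`` marks boundaries (indices where a new trial starts) whose
    crossing transitions are excluded from counts.
    """
    z = np.asarray(z, dtype=int)
    if len(z) < 2:
        raise ValueError("need at least 2 bins")
    K = int(z.max()) + 1
    counts = np.zeros((K, K))
    valid = np.ones(len(z) - 1, dtype=bool)
    if trial_edges is not None:
        for e in trial_edges:
            if 1 <= e < len(z):
                valid[e - 1] = False
    np.add.at(counts, (z[:-1][valid], z[1:][valid]), 1)
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        trans = np.where(row_sums[:, None] > 0, counts / row_sums[:, None], np.nan)
    self_p = np.diag(trans)
    dwell: dict[int, list[int]] = {k: [] for k in range(K)}
    run_start = 0
    for t in range(1, len(z) + 1):
        if t == len(z) or z[t] != z[t - 1]:
            dwell[z[run_start]].append(t - run_start)
            run_start = t
    return trans, self_p, {k: np.asarray(v) for k, v in dwell.items()}


def quartile_levels(values: np.ndarray, descending: bool = False) -> np.ndarray:
    """Quartile labels 1–4.  Ascending gives DV1 (lowest) … DV4 (highest);
    ``descending=True`` reverses for competitive-ability C1 (highest) … C4.
    Ties spanning a boundary fall in the lower bin."""
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 values")
    qs = np.quantile(values, [0.25, 0.5, 0.75])
    labels = 1 + np.searchsorted(qs, values, side="left")
    if descending:
        labels = 5 - labels
    return labels


def attractor_scores(A: np.ndarray):
    """Eigenvalue time constants τ = |1 / ln|λ||, the attractor stability
    score (max τ) and the line-attractor score log₂(τ_max / τ_second).

    |λ| = 1 yields τ = +inf (flagged); |λ| = 0 yields τ = 0.  Equal top
    magnitudes (e.g. a conjugate pair) give a line score of exactly 0.
    """
    lam = np.linalg.eigvals(np.asarray(A, dtype=float))
    mags = np.abs(lam)
    tau = np.empty_like(mags)
    for i, m in enumerate(mags):
        if m == 0:
            tau[i] = 0.0
        elif np.isclose(m, 1.0, atol=1e-12):
            tau[i] = np.inf
        else:
            tau[i] = abs(1.0 / np.log(m))
    order = np.argsort(tau)[::-1]
    tau_sorted = tau[order]
    stability = tau_sorted[0]
    if len(tau_sorted) < 2 or tau_sorted[1] == 0:
        line_score = np.inf
    elif np.isclose(tau_sorted[0], tau_sorted[1], rtol=1e-9):
        line_score = 0.0
    else:
        line_score = float(np.log2(tau_sorted[0] / tau_sorted[1]))
    return {
        "eigenvalues": lam,
        "time_constants": tau_sorted,
        "stability": float(stability),
        "line_attractor_score": line_score,
        "has_unit_eigenvalue": bool(np.isclose(mags, 1.0, atol=1e-12).any()),
    }


def sequentiality_index(
    rates: np.ndarray,
    n_shuffles: int = 1000,
    seed: int = 0,
    ridge_halfwidth: int | None = None,
):
    """Scalar sequentiality of a (units × time) rate matrix, with a circular
    shift shuffle null.

    The index averages (a) the normalized entropy of the distribution of
    per-unit peak times and (b) a normalized ridge-to-background contrast:
    mean rate in a window around each unit's peak versus elsewhere.  High
    values indicate tiled, non-overlapping sequential activation.
    """
    rates = np.asarray(rates, dtype=float)
    n_units, T = rates.shape
    if n_units < 5:
        raise ValueError("need at least 5 units")
    rates = rates - rates.min()  # ridge contrast needs nonnegative activity
    if ridge_halfwidth is None:
        ridge_halfwidth = max(1, T // 20)
    rng = np.random.default_rng(seed)

    def _index(mat: np.ndarray) -> float:
        peaks = np.argmax(mat, axis=1)
        hist = np.bincount(peaks, minlength=T).astype(float)
        p = hist / hist.sum()
        nz = p > 0
        ent = -np.sum(p[nz] * np.log(p[nz])) / np.log(min(n_units, T))
        contrasts = []
        for i in range(mat.shape[0]):
            lo = max(0, peaks[i] - ridge_halfwidth)
            hi = min(T, peaks[i] + ridge_halfwidth + 1)
            ridge = mat[i, lo:hi].mean()
            bg_mask = np.ones(T, dtype=bool)
            bg_mask[lo:hi] = False
            bg = mat[i, bg_mask].mean() if bg_mask.any() else 0.0
            contrasts.append(np.log((ridge + 1e-9) / (bg + 1e-9)))
        contrast = float(np.mean(contrasts))
        return 0.5 * (ent + contrast / (1.0 + abs(contrast)))

    obs = _index(rates)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shifts = rng.integers(0, T, size=n_units)
        shuffled = np.stack([np.roll(rates[i], shifts[i]) for i in range(n_units)])
        null[s] = _index(shuffled)
    return {"index": float(obs), "null": null,
            "percentile": float(np.mean(obs > null) * 100.0)}
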