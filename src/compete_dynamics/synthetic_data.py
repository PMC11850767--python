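"""Synthetic-data generation with known ground truth.

Emulates every input the analysis pipeline consumes: switching-model latents
with one point-attractor state and rotational states, spike/rate emissions,
behavior labels coupled to rotational phase, scripted two-mouse pose episodes
and drifting unit waveforms with log-normal-mixture inter-spike intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dynamics_metrics
from .rslds import LatentTrajectory, RSLDSParams, transition_probs, step

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_rotational_params",
    "make_line_attractor_params",
    "simulate_session",
    "behavior_from_phase",
    "gen_pose_session",
    "gen_unit_days",
    "POSE_NODES",
    "BEHAVIOR_CLASSES",
]

BEHAVIOR_CLASSES = ("other", "snatch", "chase", "retreat")

# smallest node set supporting the full 26-feature panel
POSE_NODES = ("nose", "left_ear", "right_ear", "head", "body_centroid", "tail_base")

DEFAULT_BEHAVIOR_RULE = {
    (0.0, 90.0): "other",
    (90.0, 180.0): "snatch",
    (180.0, 270.0): "chase",
    (270.0, 360.0): "retreat",
}


@dataclass
class SimConfig:
    """Simulation settings.  ``bin_s`` defaults to the 500 ms convention used
    throughout the behavioral and neural analyses."""

    n_states: int = 3
    n_latent: int = 6
    n_units: int = 30
    n_timesteps: int = 2000
    bin_s: float = 0.5
    seed: int = 0
    emission_kind: str = "gaussian"
    emission_noise_sd: float = 0.5
    process_noise_sd: float = 0.5
    behavior_rule: dict = field(default_factory=lambda: dict(DEFAULT_BEHAVIOR_RULE))

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if self.n_latent < 2:
            raise ValueError("n_latent must be >= 2 (need a rotation plane)")
        if self.bin_s <= 0:
            raise ValueError("bin_s must be positive")
        _check_rule(self.behavior_rule)


@dataclass
class GroundTruth:
    params: RSLDSParams
    latents: LatentTrajectory
    behavior_labels: np.ndarray | None = None
    unit_identity_map: dict | None = None


def _check_rule(rule: dict) -> None:
    intervals = sorted(rule.keys())
    lo = 0.0
    for a, b in intervals:
        if not np.isclose(a, lo):
            raise ValueError("behavior rule intervals must partition [0, 360)")
        if b <= a:
            raise ValueError("behavior rule intervals must be increasing")
        lo = b
    if not np.isclose(lo, 360.0):
        raise ValueError("behavior rule intervals must partition [0, 360)")


def _zero_inputs(K: int, D: int, N: int, M: int = 1):
    return (
        np.zeros((K, M)),
        [np.zeros((D, M)) for _ in range(K)],
        [np.zeros((N, M)) for _ in range(K)],
    )


def _random_emission(rng: np.random.Generator, N: int, D: int) -> np.ndarray:
    """Full-column-rank emission with unit-norm columns."""
    C = rng.standard_normal((N, D))
    q, _ = np.linalg.qr(C)
    return q[:, :D] * np.sqrt(N / D)


def make_rotational_params(
    cfg: SimConfig,
    rho: float = 0.98,
    rho_attractor: float = 0.9,
    omega_deg: float = 10.0,
) -> RSLDSParams:
    """Parameters with a contracting point-attractor state 1 and rotational
    states carrying a 2D rotation block (ρ = 0.98, ω = 10°/step by default).

    The recurrent weights point at staggered directions in the rotation
    plane so the active discrete state tracks rotational phase, and each
    state's affine offset places its fixed point one sector ahead of its own
    phase sector — the switching flow then sustains a rotating loop instead
    of collapsing into a single state.
    """
    K, D, N = cfg.n_states, cfg.n_latent, cfg.n_units
    rng = np.random.default_rng(cfg.seed)

    def rot_block(r, w_deg):
        w = np.radians(w_deg)
        return r * np.array([[np.cos(w), -np.sin(w)], [np.sin(w), np.cos(w)]])

    radius = 3.0
    sector_centers = [45.0 + 360.0 * k / K for k in range(K)]
    A, b, Q = [], [], []
    for k in range(K):
        Ak = 0.8 * np.eye(D)
        Ak[:2, :2] = rot_block(rho_attractor if k == 0 else rho, omega_deg)
        fp = np.zeros(D)
        ahead = np.radians(sector_centers[k] + 90.0)
        fp[:2] = radius * np.array([np.cos(ahead), np.sin(ahead)])
        A.append(Ak)
        b.append((np.eye(D) - Ak) @ fp)
    for _ in range(K):
        Q.append(cfg.process_noise_sd**2 * np.eye(D))

    # recurrent partition of the rotation plane by phase sector
    R = np.zeros((K, D))
    kappa = 2.5
    for k in range(K):
        ang = np.radians(sector_centers[k])
        R[k, :2] = kappa * np.array([np.cos(ang), np.sin(ang)])
    P = np.full((K, K), 0.2 / (K - 1))
    np.fill_diagonal(P, 0.8)

    C = _random_emission(rng, N, D)
    d = rng.uniform(1.0, 4.0, size=N) if cfg.emission_kind == "poisson" else \
        rng.uniform(2.0, 8.0, size=N)
    if cfg.emission_kind == "poisson":
        # keep log-rates in a sane range (latent radius is ~10)
        C = 0.03 * C
        d = np.log(d)
    S = cfg.emission_noise_sd**2 * np.eye(N)
    W, V, F = _zero_inputs(K, D, N)
    return RSLDSParams(
        K=K, D=D, N=N, P=P, R=R, W=W,
        A=A, b=b, V=V, Q=Q,
        C=[C] * K, d=[d] * K, F=F, S=[S if cfg.emission_kind == "gaussian"
                                      else np.zeros((N, N))] * K,
        emission_kind=cfg.emission_kind,
    )


def make_line_attractor_params(
    cfg: SimConfig,
    line_state: int = 2,
    slow_eig: float = 0.999,
    fast_eig: float = 0.8,
) -> RSLDSParams:
    """Rotational parameter set whose ``line_state`` instead carries one
    near-unit eigenvalue (default 0.999) with all others contracting fast,
    i.e. a line attractor: its line-attractor score exceeds 1."""
    params = make_rotational_params(cfg)
    D = cfg.n_latent
    rng = np.random.default_rng(cfg.seed + 1)
    eigs = np.full(D, fast_eig)
    eigs[0] = slow_eig
    # random similarity transform keeps the eigenvalues exactly
    B = rng.standard_normal((D, D))
    while abs(np.linalg.det(B)) < 1e-3:
        B = rng.standard_normal((D, D))
    A_line = B @ np.diag(eigs) @ np.linalg.inv(B)
    params.A[line_state] = A_line
    params.b[line_state] = np.zeros(D)
    return params


def simulate_session(
    params: RSLDSParams, cfg: SimConfig, noise_free: bool = False
) -> tuple[LatentTrajectory, np.ndarray, GroundTruth]:
    """Sample one session from the generative model.

    Returns the latent trajectory, the (N, T) rate/count matrix and a
    GroundTruth bundle.  ``noise_free=True`` zeroes all stochasticity and
    replaces sampled transitions by the argmax (deterministic oracle mode).
    """
    T = cfg.n_timesteps
    D, N, K = params.D, params.N, params.K
    rng = np.random.default_rng(cfg.seed)
    M = params.W.shape[1]
    u = np.zeros((T, M))
    z = np.empty(T, dtype=int)
    x = np.empty((T, D))
    y = np.empty((T, N))

    x_prev = np.zeros(D)
    x_prev[:2] = 3.0 * np.array([np.cos(np.radians(45.0)),
                                 np.sin(np.radians(45.0))])
    z[0] = 0
    x[0], y[0] = step(x_prev, z[0], u[0], params, None if noise_free else rng)
    for t in range(1, T):
        p = transition_probs(z[t - 1], x[t - 1], u[t], params)
        z[t] = int(np.argmax(p)) if noise_free else int(rng.choice(K, p=p))
        x[t], y[t] = step(x[t - 1], z[t], u[t], params,
                          None if noise_free else rng)
    latents = LatentTrajectory(z=z, x=x, u=u)
    gt = GroundTruth(params=params, latents=latents)
    if cfg.behavior_rule:
        gt.behavior_labels = behavior_from_phase(latents, cfg.behavior_rule)
    return latents, y.T, gt


def rotation_phase(latents: LatentTrajectory) -> np.ndarray:
    """Rotation angle of the latent trajectory, computed with the same
    three-point construction used by the downstream dynamics metrics
    (state-1 attractor proxy, geometric median, current point)."""
    x2 = latents.x[:, :2]
    med = dynamics_metrics.geometric_median(x2)
    mask = latents.z == 0
    if mask.any():
        # attractor proxy: mean of state-1 visited points
        attractor = x2[mask].mean(axis=0)
    else:
        attractor = x2[0]
    return dynamics_metrics.rotation_angle(x2, attractor, med)


def behavior_from_phase(latents: LatentTrajectory, rule: dict) -> np.ndarray:
    """Label each bin by the behavior-rule interval containing its rotation
    angle.  A pure function of the angle series."""
    _check_rule(rule)
    if latents.x.shape[1] < 2:
        raise ValueError("need at least 2 latent dimensions")
    theta = rotation_phase(latents)
    labels = np.empty(len(theta), dtype=object)
    labels[:] = "other"
    for (a, b), cls in rule.items():
        if cls not in BEHAVIOR_CLASSES:
            raise ValueError(f"unknown behavior class {cls!r}")
        sel = (theta >= a) & (theta < b)
        labels[sel] = cls
    return labels.astype(str)


# ---------------------------------------------------------------------------
# pose generation


def _mouse_frame(center, heading_deg, body_len, head_angle_deg, rng, jitter):
    """Keypoints of one mouse as a kinematic chain: tail_base → body_centroid
    → head → nose, with ears offset from the head."""
    h = np.radians(heading_deg)
    fwd = np.array([np.cos(h), np.sin(h)])
    left = np.array([-np.sin(h), np.cos(h)])
    body_centroid = np.asarray(center, dtype=float)
    tail_base = body_centroid - 0.5 * body_len * fwd
    head = body_centroid + 0.45 * body_len * fwd
    # nose bends off the body axis by head_angle
    ha = np.radians(head_angle_deg)
    nose_dir = np.cos(ha) * fwd + np.sin(ha) * left
    nose = head + 0.25 * body_len * nose_dir
    left_ear = head + 0.12 * body_len * left - 0.03 * body_len * fwd
    right_ear = head - 0.12 * body_len * left - 0.03 * body_len * fwd
    pts = {
        "nose": nose, "left_ear": left_ear, "right_ear": right_ear,
        "head": head, "body_centroid": body_centroid, "tail_base": tail_base,
    }
    if jitter > 0:
        pts = {k: v + rng.normal(0, jitter, 2) for k, v in pts.items()}
    return pts


def gen_pose_session(
    script: list[tuple[str, float]],
    seed: int = 0,
    fps: int = 30,
    jitter: float = 0.5,
):
    """Scripted two-mouse keypoint session at 30 Hz.

    Each script entry is (behavior class, duration s).  The kinematics are
    chosen so the class signatures match their feature-space descriptions:
    snatch = noses together, bent head; chase = fast co-directed travel;
    retreat = stretched bodies moving apart fast; other = near-static and
    apart.  Returns (coords, labels): coords is (frames, 2 animals,
    6 nodes, 2) and labels the per-frame ground-truth class.
    """
    if not script:
        raise ValueError("empty script")
    for cls, dur in script:
        if dur <= 0:
            raise ValueError("durations must be positive")
        if cls not in BEHAVIOR_CLASSES:
            raise ValueError(f"unknown behavior class {cls!r}")
    rng = np.random.default_rng(seed)
    frames_coords = []
    labels = []
    body_len = 60.0  # px
    arena = 400.0
    for cls, dur in script:
        n = int(round(dur * fps))
        for i in range(n):
            t = i / max(n - 1, 1)
            if cls == "snatch":
                # mice face each other, noses nearly touching, heads bent
                cA = np.array([arena / 2 - 0.72 * body_len, arena / 2])
                cB = np.array([arena / 2 + 0.72 * body_len, arena / 2])
                mA = _mouse_frame(cA, 0.0, body_len, 55.0, rng, jitter)
                mB = _mouse_frame(cB, 180.0, body_len, -55.0, rng, jitter)
            elif cls == "chase":
                # A pursues B, both moving fast in the same direction
                speed = 6.0  # px / frame
                base = np.array([arena * 0.2 + speed * i, arena / 2])
                mB = _mouse_frame(base + [1.4 * body_len, 0], 0.0, body_len,
                                  0.0, rng, jitter)
                mA = _mouse_frame(base, 0.0, body_len, 0.0, rng, jitter)
            elif cls == "retreat":
                # stretched bodies, moving apart quickly
                sep = 2.0 * body_len + 7.0 * i
                cA = np.array([arena / 2 - sep / 2, arena / 2])
                cB = np.array([arena / 2 + sep / 2, arena / 2])
                mA = _mouse_frame(cA, 180.0, 1.35 * body_len, 0.0, rng, jitter)
                mB = _mouse_frame(cB, 0.0, 1.35 * body_len, 0.0, rng, jitter)
            else:  # other: static, well apart
                cA = np.array([arena * 0.25, arena * 0.25])
                cB = np.array([arena * 0.75, arena * 0.75])
                mA = _mouse_frame(cA, 90.0, body_len, 0.0, rng, jitter)
                mB = _mouse_frame(cB, -90.0, body_len, 0.0, rng, jitter)
            frame = np.stack([
                np.stack([mA[nd] for nd in POSE_NODES]),
                np.stack([mB[nd] for nd in POSE_NODES]),
            ])
            frames_coords.append(frame)
            labels.append(cls)
    coords = np.stack(frames_coords)
    return coords, np.asarray(labels)


# ---------------------------------------------------------------------------
# unit waveform / ISI generation


def _waveform_template(rng: np.random.Generator, n_samples: int = 48) -> np.ndarray:
    """Sum of 2–3 Gaussian-derivative lobes — a stylized extracellular spike."""
    t = np.linspace(-1, 1, n_samples)
    wf = np.zeros(n_samples)
    n_lobes = rng.integers(2, 6)
    for _ in range(n_lobes):
        center = rng.uniform(-0.6, 0.6)
        width = rng.uniform(0.04, 0.3)
        amp = rng.uniform(0.3, 1.5) * rng.choice([-1, 1])
        u = (t - center) / width
        wf += amp * (-u) * np.exp(-0.5 * u**2)
    return wf / np.max(np.abs(wf))


def gen_unit_days(
    n_units: int,
    n_days: int,
    drift_sd: float,
    seed: int = 0,
    n_isi: int = 5000,
    n_distractors: int = 0,
):
    """Per-day unit records with known cross-day identity.

    Each unit keeps a fixed waveform template, jittered day-to-day with SD
    ``drift_sd`` (in template-amplitude units), and a fixed three-component
    log-normal ISI mixture sampled afresh each day.  Distractor units get
    unrelated templates and mixtures.  Returns (days, identity_map) where
    ``days[d]`` is a list of dicts with keys 'unit', 'waveform', 'isis',
    'isih_params' and identity_map maps (day, unit) → true unit id.
    """
    if drift_sd < 0:
        raise ValueError("drift_sd must be >= 0")
    rng = np.random.default_rng(seed)
    templates = [_waveform_template(rng) for _ in range(n_units + n_distractors)]
    mixtures = []
    for _ in range(n_units + n_distractors):
        mu = np.sort(rng.uniform(np.log(0.001), np.log(1.0), 3))
        sigma = rng.uniform(0.15, 0.8, 3)
        pi = rng.dirichlet([1.0, 1.0, 1.0])
        mixtures.append((mu, sigma, pi))

    days = []
    identity = {}
    for d in range(n_days):
        recs = []
        for uidx in range(n_units + (n_distractors if d > 0 else 0)):
            wf = templates[uidx] + rng.normal(0, drift_sd, templates[uidx].shape)
            mu, sigma, pi = mixtures[uidx]
            comp = rng.choice(3, size=n_isi, p=pi)
            isis = np.exp(rng.normal(mu[comp], sigma[comp]))
            recs.append({
                "unit": uidx, "waveform": wf, "isis": isis,
                "isih_params": np.concatenate([mu, sigma, pi[:2]]),
            })
            identity[(d, uidx)] = uidx
        days.append(recs)
    return days, identity
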