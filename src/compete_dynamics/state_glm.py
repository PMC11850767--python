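"""State-specific multinomial GLM decoding of behavior.

One multinomial GLM per discrete state maps a cue vector s_t (z-scored
latent dimensions plus distance and facing angle) to behavior probabilities

    P(behavior = i | s_t) = exp(F_i · s_t) / Σ_j exp(F_j · s_t)

with four filters per state, the 'other' filter pinned at zero for
identifiability.  Fitting maximizes the log-likelihood minus a smoothness
penalty λ Σ_i Σ_j (F_i[j+1] − F_i[j])² on adjacent filter coefficients; the
problem is concave so the optimum is unique and deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .synthetic_data import BEHAVIOR_CLASSES

__all__ = [
    "predict_proba",
    "fit_state_glm",
    "chance_model",
    "decode",
    "raster_from_filters",
    "BEHAVIOR_CLASSES",
]

_N_CLASSES = 4
_CAP = 20.0  # weight cap when a class is absent from a state


def predict_proba(s_t: np.ndarray, filters: np.ndarray) -> np.ndarray:
    """Behavior-probability simplex for one cue vector under one state's
    4 × n_cues filter bank."""
    s_t = np.asarray(s_t, dtype=float)
    if not np.all(np.isfinite(s_t)):
        raise ValueError("cue vector must be finite")
    filters = np.asarray(filters, dtype=float)
    if filters.shape[1] != len(s_t):
        raise ValueError("cue/filter length mismatch")
    logits = filters @ s_t
    p = np.exp(logits - logsumexp(logits))
    return p / p.sum()


def _smoothness(F: np.ndarray) -> float:
    d = np.diff(F, axis=1)
    return float(np.sum(d**2))


def _smoothness_grad(F: np.ndarray) -> np.ndarray:
    g = np.zeros_like(F)
    d = np.diff(F, axis=1)
    g[:, :-1] -= 2 * d
    g[:, 1:] += 2 * d
    return g


def fit_state_glm(
    cues: np.ndarray,
    behaviors: np.ndarray,
    z: np.ndarray,
    smooth_lambda: float = 0.1,
) -> dict[int, np.ndarray]:
    """Fit one penalized multinomial GLM per discrete state.

    ``cues`` is (T, n_cues) z-scored, ``behaviors`` holds class names from
    the four-class set, ``z`` the active state per bin.  Returns
    state → (4, n_cues) filters with row 0 ('other') all zero.  States where
    a class never occurs get that class's weights driven down; they are
    capped at ±20 with a warning.
    """
    cues = np.asarray(cues, dtype=float)
    z = np.asarray(z, dtype=int)
    y = np.array([BEHAVIOR_CLASSES.index(b) for b in behaviors])
    n_cues = cues.shape[1]
    out: dict[int, np.ndarray] = {}
    for state in np.unique(z):
        mask = z == state
        if mask.sum() < 20:
            raise ValueError(f"state {state} has fewer than 20 bins")
        Xs, ys = cues[mask], y[mask]
        if len(np.unique(ys)) < 2:
            raise ValueError(f"state {state} has a single behavior class")
        present = np.bincount(ys, minlength=_N_CLASSES) > 0

        def negobj(theta):
            F = np.zeros((_N_CLASSES, n_cues))
            F[1:] = theta.reshape(_N_CLASSES - 1, n_cues)
            logits = Xs @ F.T
            lse = logsumexp(logits, axis=1)
            ll = logits[np.arange(len(ys)), ys].sum() - lse.sum()
            pen = smooth_lambda * _smoothness(F[1:])
            # gradient
            p = np.exp(logits - lse[:, None])
            p[np.arange(len(ys)), ys] -= 1.0
            gF = p.T @ Xs                       # (4, n_cues)
            gF[1:] += smooth_lambda * _smoothness_grad(F[1:])
            return -(ll - pen), gF[1:].ravel()

        theta0 = np.zeros((_N_CLASSES - 1) * n_cues)
        res = minimize(negobj, theta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 500, "gtol": 1e-8})
        F = np.zeros((_N_CLASSES, n_cues))
        F[1:] = res.x.reshape(_N_CLASSES - 1, n_cues)
        if not present.all() and np.any(np.abs(F) > _CAP):
            import warnings

            warnings.warn(
                f"state {state}: absent classes drove weights to the ±{_CAP} cap",
                RuntimeWarning, stacklevel=2)
        F = np.clip(F, -_CAP, _CAP)
        out[int(state)] = F
    return out


def chance_model(behaviors: np.ndarray):
    """Constant-probability model from empirical class frequencies N_i / N."""
    y = np.asarray(behaviors)
    if len(y) == 0:
        raise ValueError("need at least one bin")
    freqs = np.array([(y == cls).mean() for cls in BEHAVIOR_CLASSES])
    nz = freqs > 0
    loglik = float(np.sum([np.log(freqs[BEHAVIOR_CLASSES.index(b)])
                           for b in y if freqs[BEHAVIOR_CLASSES.index(b)] > 0]))
    return {"probs": freqs, "loglik": loglik,
            "accuracy": float(freqs.max())}


def decode(cues: np.ndarray, z: np.ndarray,
           filters: dict[int, np.ndarray],
           behaviors: np.ndarray | None = None):
    """Argmax-decode behavior per bin with the active state's filters.

    Ties go to the lowest class index (other < snatch < chase < retreat).
    With ``behaviors`` given also returns accuracy, confusion matrix and the
    chance-model accuracy on the same bins.
    """
    cues = np.asarray(cues, dtype=float)
    z = np.asarray(z, dtype=int)
    preds = []
    for t in range(len(cues)):
        if z[t] not in filters:
            raise ValueError(f"no filters for state {z[t]}")
        p = predict_proba(cues[t], filters[z[t]])
        preds.append(int(np.argmax(p)))  # argmax takes first max: lowest index
    pred_classes = np.asarray([BEHAVIOR_CLASSES[i] for i in preds])
    out = {"predictions": pred_classes}
    if behaviors is not None:
        y = np.asarray(behaviors)
        out["accuracy"] = float(np.mean(pred_classes == y))
        conf = np.zeros((_N_CLASSES, _N_CLASSES), dtype=int)
        for t in range(len(y)):
            conf[BEHAVIOR_CLASSES.index(y[t]), preds[t]] += 1
        out["confusion"] = conf
        out["chance_accuracy"] = chance_model(y)["accuracy"]
    return out


def loglik(cues: np.ndarray, z: np.ndarray, behaviors: np.ndarray,
           filters: dict[int, np.ndarray]) -> float:
    """Log-likelihood of a behavior sequence under the fitted state GLMs."""
    total = 0.0
    for t in range(len(cues)):
        p = predict_proba(cues[t], filters[int(z[t])])
        total += np.log(max(p[BEHAVIOR_CLASSES.index(behaviors[t])], 1e-300))
    return float(total)


def raster_from_filters(
    cues: np.ndarray,
    z: np.ndarray,
    filters: dict[int, np.ndarray],
    mode: str = "full",
    single_state: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Sample a behavior raster from predicted probabilities.

    ``mode='full'`` uses each bin's active-state filters; ``mode='single'``
    applies ``single_state``'s filters to every bin.
    """
    rng = np.random.default_rng(seed)
    cues = np.asarray(cues, dtype=float)
    z = np.asarray(z, dtype=int)
    out = []
    for t in range(len(cues)):
        k = single_state if mode == "single" else int(z[t])
        p = predict_proba(cues[t], filters[k])
        out.append(BEHAVIOR_CLASSES[rng.choice(_N_CLASSES, p=p)])
    return np.asarray(out)
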