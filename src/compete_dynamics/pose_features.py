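"""Two-animal pose featurization and behavior classification.

Turns per-frame keypoint tracks (30 Hz, two mice, six nodes each) into a
26-dimensional feature space — 9 self features per mouse plus 8 interaction
features — then 500 ms feature clips, hierarchical behavioral-motif
clusters, a four-class behavior labelling (snatch / chase / retreat /
other), run-length event metrics and food-competition possession scores.

Distances are in pixels; angles in degrees.  All angles are undirected in
[0, 180°] except the displacement (travel-direction) angle, which lives in
[0, 360°).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .synthetic_data import BEHAVIOR_CLASSES, POSE_NODES

__all__ = [
    "FEATURE_NAMES",
    "PUBLISHED_MOTIF_PRESET",
    "compute_features",
    "make_clips",
    "cluster_motifs",
    "classify_behavior",
    "event_metrics",
    "occupancy_score",
    "detection_eval",
]

_NODE_IDX = {n: i for i, n in enumerate(POSE_NODES)}

_SELF_FEATURES = (
    "head_length", "body_length", "head_body_angle",
    "left_ear_nose_length", "right_ear_nose_length",
    "left_ear_body_angle", "right_ear_body_angle",
    "displacement_angle", "displacement_distance",
)
_INTERACTION_FEATURES = (
    "body_body_angle", "head_head_angle",
    "nose_nose_distance", "nose_nose_angle",
    "tailA_noseB_distance", "tailB_noseA_distance",
    "tailA_noseB_angle", "tailB_noseA_angle",
)
FEATURE_NAMES = tuple(
    [f"{f}_A" for f in _SELF_FEATURES]
    + [f"{f}_B" for f in _SELF_FEATURES]
    + list(_INTERACTION_FEATURES)
)

# motif → class preset mirroring the published cluster assignments
# (17, 18 → snatch; 2, 4 → retreat; 1, 6, 8 noise; 16 → other)
PUBLISHED_MOTIF_PRESET = {
    "mapping": {17: "snatch", 18: "snatch", 2: "retreat", 4: "retreat",
                16: "other"},
    "noise": [1, 6, 8],
}


def _undirected_angle(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Angle in degrees ∈ [0, 180] between direction vectors, rows paired."""
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.einsum("...i,...i->...", v1, v2) / (n1 * n2)
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def _self_features(coords: np.ndarray, animal: int) -> np.ndarray:
    c = coords[:, animal]  # (T, nodes, 2)
    nose = c[:, _NODE_IDX["nose"]]
    head = c[:, _NODE_IDX["head"]]
    body = c[:, _NODE_IDX["body_centroid"]]
    tail = c[:, _NODE_IDX["tail_base"]]
    le = c[:, _NODE_IDX["left_ear"]]
    re = c[:, _NODE_IDX["right_ear"]]

    head_len = np.linalg.norm(nose - head, axis=1)
    body_len = np.linalg.norm(head - tail, axis=1)
    hb_angle = _undirected_angle(nose - head, head - body)
    le_nose = np.linalg.norm(le - nose, axis=1)
    re_nose = np.linalg.norm(re - nose, axis=1)
    le_body = _undirected_angle(le - body, head - body)
    re_body = _undirected_angle(re - body, head - body)

    disp = np.diff(body, axis=0, prepend=body[:1])
    disp_dist = np.linalg.norm(disp, axis=1)
    disp_angle = np.degrees(np.arctan2(disp[:, 1], disp[:, 0])) % 360.0
    return np.column_stack([
        head_len, body_len, hb_angle, le_nose, re_nose, le_body, re_body,
        disp_angle, disp_dist,
    ])


def compute_features(coords: np.ndarray) -> np.ndarray:
    """Per-frame 26-feature matrix from (frames, 2, 6 nodes, 2) coordinates.

    Raises on non-finite coordinates or single-frame sessions (displacement
    needs consecutive frames).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 4 or coords.shape[1] != 2 or coords.shape[2] != len(POSE_NODES):
        raise ValueError(
            f"expected (frames, 2, {len(POSE_NODES)}, 2) coordinates, "
            f"got {coords.shape}")
    if len(coords) < 2:
        raise ValueError("need at least 2 frames (displacement undefined)")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite (interpolate gaps first)")

    fA = _self_features(coords, 0)
    fB = _self_features(coords, 1)

    def node(animal, name):
        return coords[:, animal, _NODE_IDX[name]]

    axisA = node(0, "head") - node(0, "tail_base")
    axisB = node(1, "head") - node(1, "tail_base")
    headA = node(0, "nose") - node(0, "head")
    headB = node(1, "nose") - node(1, "head")
    bb_angle = _undirected_angle(axisA, axisB)
    hh_angle = _undirected_angle(headA, headB)
    nn_vec = node(1, "nose") - node(0, "nose")
    nn_dist = np.linalg.norm(nn_vec, axis=1)
    nn_angle = _undirected_angle(nn_vec, axisA)
    tAnB = node(1, "nose") - node(0, "tail_base")
    tBnA = node(0, "nose") - node(1, "tail_base")
    inter = np.column_stack([
        bb_angle, hh_angle, nn_dist, nn_angle,
        np.linalg.norm(tAnB, axis=1), np.linalg.norm(tBnA, axis=1),
        _undirected_angle(tAnB, axisA), _undirected_angle(tBnA, axisB),
    ])
    return np.column_stack([fA, fB, inter])


@dataclass
class FeatureClip:
    start_frame: int
    feature_vector: np.ndarray        # 26 z-scored values
    motif_id: int | None = None
    behavior_class: str | None = None


def make_clips(features: np.ndarray, fps: float = 30.0,
               clip_ms: float = 500.0) -> list[FeatureClip]:
    """Average frame features inside 500 ms windows then z-score across
    clips.  Zero-variance dimensions z-score to 0 (flagged via nan_to_num)."""
    features = np.asarray(features, dtype=float)
    frames_per_clip = int(round(fps * clip_ms / 1000.0))
    n_clips = len(features) // frames_per_clip
    if n_clips < 1:
        raise ValueError("session shorter than one clip")
    means = np.stack([
        features[i * frames_per_clip:(i + 1) * frames_per_clip].mean(axis=0)
        for i in range(n_clips)
    ])
    mu = means.mean(axis=0)
    sd = means.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (means - mu) / sd, 0.0)
    return [FeatureClip(start_frame=i * frames_per_clip, feature_vector=z[i])
            for i in range(n_clips)]


def cluster_motifs(
    clips: list[FeatureClip],
    n_clusters: int | None = None,
    cut_height: float | None = None,
    method: str = "ward",
    noise_clusters: list[int] | None = None,
):
    """Agglomerative clustering of z-scored clip vectors (Euclidean distance,
    Ward linkage by default).  Returns (labels, linkage matrix); labels are
    1-based; clips in declared noise clusters get label −1.
    """
    if len(clips) < 2:
        raise ValueError("need at least 2 clips")
    X = np.stack([c.feature_vector for c in clips])
    if n_clusters is not None and n_clusters > len(clips):
        raise ValueError("n_clusters exceeds number of clips")
    Z = linkage(X, method=method, metric="euclidean")
    if n_clusters is not None:
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    elif cut_height is not None:
        labels = fcluster(Z, t=cut_height, criterion="distance")
    else:
        raise ValueError("give n_clusters or cut_height")
    labels = np.asarray(labels, dtype=int)
    if noise_clusters:
        labels = np.where(np.isin(labels, noise_clusters), -1, labels)
    for clip, lab in zip(clips, labels):
        clip.motif_id = int(lab)
    return labels, Z


def classify_behavior(motif_labels: np.ndarray, mapping: dict[int, str],
                      noise: list[int] | None = None) -> np.ndarray:
    """Map motif ids to the four behavior classes.  Noise motifs (label −1 or
    listed in ``noise``) are dropped (returned as None); an unmapped
    non-noise motif is an error."""
    noise = set(noise or [])
    out = []
    for lab in np.asarray(motif_labels):
        lab = int(lab)
        if lab == -1 or lab in noise:
            out.append(None)
        elif lab in mapping:
            cls = mapping[lab]
            if cls not in BEHAVIOR_CLASSES:
                raise ValueError(f"unknown behavior class {cls!r}")
            out.append(cls)
        else:
            raise ValueError(f"motif {lab} has no class mapping")
    return np.asarray(out, dtype=object)


def event_metrics(classes: np.ndarray, clip_s: float = 0.5) -> pd.DataFrame:
    """Run-length event accounting: an event is a maximal run of one class.

    Returns a table with event count, total duration and per-event durations
    for each of the four classes.
    """
    classes = [c for c in np.asarray(classes, dtype=object)]
    rows = {cls: [] for cls in BEHAVIOR_CLASSES}
    i = 0
    while i < len(classes):
        j = i
        while j < len(classes) and classes[j] == classes[i]:
            j += 1
        if classes[i] in rows:
            rows[classes[i]].append((j - i) * clip_s)
        i = j
    return pd.DataFrame([
        {"behavior": cls, "events": len(durs),
         "total_duration_s": float(sum(durs)),
         "durations_s": durs}
        for cls, durs in rows.items()
    ])


def occupancy_score(timeline: list[tuple[float, str]], session_end: float,
                    hold_threshold_s: float = 3.0):
    """Food-competition possession accounting under the 3 s defender rule.

    ``timeline`` is a sorted list of (time, holder) change points with holder
    in {'A', 'B', 'none'}.  The first mouse to hold is the defender; a
    challenger's take only becomes a defender switch if held at least 3 s,
    otherwise it is logged as a failed bout (and the defender keeps accruing
    defender status when the pellet returns).  Returns a dict with cumulative
    occupancy per mouse (time as defender), the defender timeline, and bout
    win rates.
    """
    events = sorted(timeline)
    for (t1, _), (t2, _) in zip(events, events[1:]):
        if t2 < t1:
            raise ValueError("overlapping possession claims")
    # first actual holder
    holders = [(t, h) for t, h in events if h in ("A", "B")]
    occupancy = {"A": 0.0, "B": 0.0}
    bouts = {"A": {"won": 0, "lost": 0}, "B": {"won": 0, "lost": 0}}
    defender_timeline = []
    if not holders:
        return {"occupancy": occupancy, "defender_timeline": [],
                "bouts": bouts}
    defender = holders[0][1]
    seg_start = holders[0][0]
    # walk holder changes; a challenger hold >= threshold switches the defender
    idx = [i for i, (t, h) in enumerate(events) if t >= holders[0][0]]
    evs = [events[i] for i in idx]
    for i, (t, h) in enumerate(evs):
        if h in ("A", "B") and h != defender:
            t_end = evs[i + 1][0] if i + 1 < len(evs) else session_end
            held = t_end - t
            if held >= hold_threshold_s:
                # defender switch at the take time
                occupancy[defender] += t - seg_start
                defender_timeline.append((seg_start, t, defender))
                bouts[h]["won"] += 1
                defender = h
                seg_start = t
            else:
                bouts[h]["lost"] += 1
    occupancy[defender] += session_end - seg_start
    defender_timeline.append((seg_start, session_end, defender))
    win_rate = {}
    for m in ("A", "B"):
        tot = bouts[m]["won"] + bouts[m]["lost"]
        win_rate[m] = bouts[m]["won"] / tot if tot else np.nan
    return {"occupancy": occupancy, "defender_timeline": defender_timeline,
            "bouts": bouts, "win_rate": win_rate}


def _iou(box1, box2) -> float:
    x1 = max(box1[0], box2[0]); y1 = max(box1[1], box2[1])
    x2 = min(box1[2], box2[2]); y2 = min(box1[3], box2[3])
    inter = max(0.0, x2 - x1) * max(0.0, y2 - y1)
    a1 = (box1[2] - box1[0]) * (box1[3] - box1[1])
    a2 = (box2[2] - box2[0]) * (box2[3] - box2[1])
    union = a1 + a2 - inter
    return inter / union if union > 0 else 0.0


def detection_eval(
    pred_boxes, true_boxes, pred_cats=None, true_cats=None,
    pred_points=None, true_points=None, iou_threshold: float = 0.60,
):
    """Detection precision (TP iff category matches and IoU > threshold) and
    keypoint RMSE (mean Euclidean pixel distance per node)."""
    pred_boxes = np.asarray(pred_boxes, dtype=float)
    true_boxes = np.asarray(true_boxes, dtype=float)
    n = len(pred_boxes)
    if pred_cats is None:
        pred_cats = np.zeros(n)
    if true_cats is None:
        true_cats = np.zeros(len(true_boxes))
    tp = fp = 0
    for i in range(n):
        ok = (pred_cats[i] == true_cats[i]
              and _iou(pred_boxes[i], true_boxes[i]) > iou_threshold)
        tp += ok
        fp += not ok
    precision = tp / (tp + fp) if (tp + fp) else np.nan
    rmse = None
    if pred_points is not None and true_points is not None:
        d = np.linalg.norm(np.asarray(pred_points, float)
                           - np.asarray(true_points, float), axis=-1)
        rmse = float(d.mean())
    return {"precision": float(precision), "tp": int(tp), "fp": int(fp),
            "rmse": rmse}
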