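"""End-to-end orchestration: simulate → features → fit → dynamics → GLM →
cross-correlation, with a manifest recording seeds, parameters and output
hashes so a rerun with the same config is bit-identical."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import dynamics_metrics, io, pose_features, rslds, state_glm, synthetic_data
from . import longitudinal

__all__ = ["default_config", "run_pipeline"]


def default_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "simulate": {
            "n_states": 3, "n_latent": 2, "n_units": 30, "n_timesteps": 1200,
            "emission_noise_sd": 0.1, "process_noise_sd": 0.05,
        },
        "pose": {"script": [["other", 2.0], ["snatch", 2.0], ["chase", 2.0],
                            ["retreat", 2.0]]},
        "fit": {"K": 3, "D": 2, "max_iter": 40},
        "glm": {"smooth_lambda": 0.1, "train_frac": 0.8},
        "crosscorr": {"n_perm": 500},
    }


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run every stage on synthetic data and write a manifest.

    Returns the manifest dict (also written to ``out_dir/manifest.json``).
    """
    known = {"seed", "simulate", "pose", "fit", "glm", "crosscorr"}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown pipeline stage(s): {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])

    # --- simulate neural session
    sim = config["simulate"]
    cfg = synthetic_data.SimConfig(seed=seed, **sim)
    params = synthetic_data.make_rotational_params(cfg)
    latents, rates, gt = synthetic_data.simulate_session(params, cfg)
    io.write_rates(out / "rates.csv", rates)

    # --- pose session + features + events
    coords, pose_labels = synthetic_data.gen_pose_session(
        [tuple(e) for e in config["pose"]["script"]], seed=seed)
    io.write_pose_csv(out / "poses.csv", coords)
    feats = pose_features.compute_features(coords)
    clips = pose_features.make_clips(feats)
    n_clusters = min(6, len(clips))
    motifs, _ = pose_features.cluster_motifs(clips, n_clusters=n_clusters)
    clip_truth = [pose_labels[c.start_frame] for c in clips]
    # majority mapping from motif to scripted class (demo ground-truth mapping)
    mapping = {}
    for m in np.unique(motifs):
        members = [clip_truth[i] for i in range(len(clips)) if motifs[i] == m]
        mapping[int(m)] = max(set(members), key=members.count)
    classes = pose_features.classify_behavior(motifs, mapping)
    events = pose_features.event_metrics(classes)
    events.drop(columns="durations_s").to_csv(out / "events.csv", index=False)

    # --- fit the switching model
    fit_cfg = config["fit"]
    fr = rslds.fit(rates, fit_cfg["K"], fit_cfg["D"], seed=seed,
                   max_iter=fit_cfg.get("max_iter", 40))
    np.savetxt(out / "posterior_z.csv", fr.z, fmt="%d")

    # --- dynamics metrics
    pca = dynamics_metrics.pca_transform(fr)
    vel = dynamics_metrics.dynamic_velocity(fr.params, fr.x, fr.z)
    trans, self_p, dwell = dynamics_metrics.transition_stats(fr.z)
    scores = [dynamics_metrics.attractor_scores(A) for A in fr.params.A]
    theta = synthetic_data.rotation_phase(latents)
    report = {
        "dynamic_velocity": vel,
        "transition_matrix": trans,
        "self_transition": self_p,
        "variance_explained": fr.variance_explained,
        "line_attractor_scores": [s["line_attractor_score"] for s in scores],
        "stability_scores": [s["stability"] for s in scores],
    }
    io.write_json(out / "dynamics_report.json", report)

    # --- state GLM on ground-truth latents + behavior
    labels = gt.behavior_labels
    cues = np.column_stack([latents.x, np.zeros(len(theta)), np.zeros(len(theta))])
    cues = (cues - cues.mean(0)) / np.maximum(cues.std(0), 1e-12)
    split = int(config["glm"]["train_frac"] * len(cues))
    filters = state_glm.fit_state_glm(
        cues[:split], labels[:split], latents.z[:split],
        smooth_lambda=config["glm"]["smooth_lambda"])
    dec = state_glm.decode(cues[split:], latents.z[split:], filters,
                           labels[split:])
    io.write_json(out / "glm_report.json", {
        "accuracy": dec["accuracy"], "chance": dec["chance_accuracy"],
        "confusion": dec["confusion"],
    })

    # --- longitudinal cross-correlation on derived daily series
    rng = np.random.default_rng(seed)
    days = 14
    neural = np.cumsum(rng.standard_normal(days))
    behave = np.roll(neural, 2) + 0.1 * rng.standard_normal(days)
    lags, r = longitudinal.cross_correlation(neural, behave)
    p = longitudinal.permutation_test(neural, behave,
                                      n=config["crosscorr"]["n_perm"], seed=seed)
    io.write_json(out / "crosscorr.json", {
        "lags": lags, "r": r,
        "optimal_lag": longitudinal.optimal_lag(lags, r), "p": p,
    })

    # --- manifest
    outputs = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "seed": seed,
        "config": config,
        "outputs": {p.name: _hash_file(p) for p in outputs},
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)
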