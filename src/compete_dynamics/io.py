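"""File formats: pose CSV/HDF5 (SLEAP-analysis layout), spike/waveform CSV,
rate matrices, fit results and reports.

CSV dialect everywhere: UTF-8, comma separator, header row, '.' decimal.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic_data import POSE_NODES

__all__ = [
    "write_pose_csv", "read_pose_csv",
    "write_pose_h5", "read_pose_h5",
    "write_spikes_csv", "read_spikes_csv",
    "write_rates", "read_rates",
    "write_waveforms_csv", "read_waveforms_csv",
    "write_json", "read_json",
]


def write_pose_csv(path, coords: np.ndarray) -> None:
    """(frames, 2, nodes, 2) → long CSV with columns frame, animal, node, x, y."""
    frames, n_animals, n_nodes, _ = coords.shape
    rows = []
    for f in range(frames):
        for a in range(n_animals):
            for nd in range(n_nodes):
                rows.append((f, a, POSE_NODES[nd],
                             coords[f, a, nd, 0], coords[f, a, nd, 1]))
    pd.DataFrame(rows, columns=["frame", "animal", "node", "x", "y"]).to_csv(
        path, index=False)


def read_pose_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    required = {"frame", "animal", "node", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"pose CSV must have columns {sorted(required)}")
    frames = int(df["frame"].max()) + 1
    node_idx = {n: i for i, n in enumerate(POSE_NODES)}
    coords = np.full((frames, 2, len(POSE_NODES), 2), np.nan)
    bad = set(df["node"]) - set(POSE_NODES)
    if bad:
        raise ValueError(f"unknown node names: {sorted(bad)}")
    coords[df["frame"], df["animal"], [node_idx[n] for n in df["node"]]] = \
        df[["x", "y"]].to_numpy()
    return coords


def write_pose_h5(path, coords: np.ndarray) -> None:
    """SLEAP-analysis-style layout: tracks (animal, node, 2, frame) plus a
    node_names dataset."""
    with h5py.File(path, "w") as f:
        f.create_dataset("tracks", data=np.transpose(coords, (1, 2, 3, 0)))
        f.create_dataset("node_names",
                         data=np.array(POSE_NODES, dtype=h5py.string_dtype()))


def read_pose_h5(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        tracks = f["tracks"][:]
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in f["node_names"][:]]
    # map nodes by name, not stored order
    order = [names.index(n) for n in POSE_NODES]
    tracks = tracks[:, order]
    return np.transpose(tracks, (3, 0, 1, 2))


def write_spikes_csv(path, spikes: dict[int, np.ndarray]) -> None:
    rows = [(u, t) for u, ts in spikes.items() for t in ts]
    pd.DataFrame(rows, columns=["unit", "t_s"]).to_csv(path, index=False)


def read_spikes_csv(path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    if not {"unit", "t_s"}.issubset(df.columns):
        raise ValueError("spike CSV must have columns unit, t_s")
    return {int(u): np.sort(g["t_s"].to_numpy())
            for u, g in df.groupby("unit")}


def write_rates(path, rates: np.ndarray) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("rates", data=rates)
    else:
        pd.DataFrame(rates).to_csv(path, index=False)


def read_rates(path) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return f["rates"][:]
    return pd.read_csv(path).to_numpy()


def write_waveforms_csv(path, waveforms: dict[int, np.ndarray]) -> None:
    units = sorted(waveforms)
    n = len(next(iter(waveforms.values())))
    df = pd.DataFrame(
        [[u, *waveforms[u]] for u in units],
        columns=["unit"] + [f"sample_{i}" for i in range(n)])
    df.to_csv(path, index=False)


def read_waveforms_csv(path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    if "unit" not in df.columns:
        raise ValueError("waveform CSV must have a 'unit' column")
    samples = [c for c in df.columns if c.startswith("sample_")]
    return {int(r["unit"]): r[samples].to_numpy(dtype=float)
            for _, r in df.iterrows()}


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(path, obj) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, cls=_NumpyEncoder)


def read_json(path):
    with open(path) as f:
        return json.load(f)
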