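"""Plain-text session I/O.

A session on disk is a directory of small text files: ``positions.csv``
(t, x, y, hd), one ``spikes_<unit>.csv`` per unit (t), ``lfp.csv``
(t, v), ``ground_truth.json`` and ``protocol.json``. Times in seconds,
positions in meters.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .types import GroundTruth, LfpSignal, SessionProtocol, SpikeTrain, Trajectory

__all__ = ["write_session", "read_session", "write_experiment", "read_experiment"]


def write_session(path, traj: Trajectory, spikes, lfp: Optional[LfpSignal] = None,
                  ground_truth=None) -> None:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "t": traj.t, "x": traj.x, "y": traj.y,
        "hd": traj.hd if traj.hd is not None else np.full(len(traj.t), np.nan),
    }).to_csv(p / "positions.csv", index=False)
    meta = {"fs": traj.fs, "arena_size": traj.arena_size,
            "units": [s.unit_id for s in spikes]}
    for s in spikes:
        pd.DataFrame({"t": s.times}).to_csv(p / f"spikes_{s.unit_id}.csv", index=False)
        meta.setdefault("spans", {})[s.unit_id] = [s.t_start, s.t_stop]
    if lfp is not None:
        pd.DataFrame({"t": lfp.t, "v": lfp.samples}).to_csv(p / "lfp.csv", index=False)
        meta["lfp_fs"] = lfp.fs
    if ground_truth is not None:
        with open(p / "ground_truth.json", "w") as fh:
            json.dump([asdict(g) for g in ground_truth], fh, indent=1)
    with open(p / "session.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_session(path) -> dict:
    p = Path(path)
    if not (p / "session.json").exists():
        raise FileNotFoundError(f"no session.json under {p}")
    with open(p / "session.json") as fh:
        meta = json.load(fh)
    pos = pd.read_csv(p / "positions.csv")
    hd = pos["hd"].to_numpy()
    traj = Trajectory(t=pos["t"].to_numpy(), x=pos["x"].to_numpy(),
                      y=pos["y"].to_numpy(), fs=meta["fs"],
                      arena_size=meta["arena_size"],
                      hd=None if np.all(np.isnan(hd)) else hd)
    spikes = []
    for uid in meta["units"]:
        times = pd.read_csv(p / f"spikes_{uid}.csv")["t"].to_numpy()
        t0, t1 = meta["spans"][uid]
        spikes.append(SpikeTrain(uid, times, t0, t1))
    out = {"trajectory": traj, "spikes": spikes}
    if (p / "lfp.csv").exists():
        lf = pd.read_csv(p / "lfp.csv")
        out["lfp"] = LfpSignal(samples=lf["v"].to_numpy(), fs=meta["lfp_fs"],
                               t_start=float(lf["t"].iloc[0]))
    if (p / "ground_truth.json").exists():
        with open(p / "ground_truth.json") as fh:
            out["ground_truth"] = [GroundTruth(**g) for g in json.load(fh)]
    return out


def write_experiment(path, bundle: dict) -> None:
    """Write a multi-session protocol bundle (from the synthetic generator)."""
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    labels = []
    for i, sess in enumerate(bundle["sessions"]):
        label = sess["label"]
        labels.append(label)
        write_session(p / f"session_{i:02d}", sess["trajectory"], sess["spikes"],
                      lfp=sess.get("lfp"),
                      ground_truth=bundle.get("population"))
    proto = bundle["protocol"]
    with open(p / "protocol.json", "w") as fh:
        json.dump({"labels": list(proto.labels),
                   "durations": list(proto.durations),
                   "remap_rotation": proto.remap_rotation,
                   "remap_shift": list(proto.remap_shift),
                   "drift_sigma": proto.drift_sigma}, fh, indent=1)


def read_experiment(path) -> dict:
    p = Path(path)
    if not (p / "protocol.json").exists():
        raise FileNotFoundError(f"no protocol.json under {p}")
    with open(p / "protocol.json") as fh:
        d = json.load(fh)
    proto = SessionProtocol(labels=tuple(d["labels"]),
                            durations=tuple(d["durations"]),
                            remap_rotation=d["remap_rotation"],
                            remap_shift=tuple(d["remap_shift"]),
                            drift_sigma=d["drift_sigma"])
    sessions = []
    for i, label in enumerate(d["labels"]):
        s = read_session(p / f"session_{i:02d}")
        s["label"] = label
        sessions.append(s)
    out = {"sessions": sessions, "protocol": proto}
    gt = sessions[0].get("ground_truth")
    if gt:
        out["population"] = gt
    return out
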