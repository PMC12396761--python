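"""Trajectory persistence: tidy CSVs, JSON summary, resolved config, and a
checksummed manifest.  Floats are written at full ``repr`` precision so a
write/read round trip reproduces every array bit-exactly."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import engagement_summary
from .config import RunConfig, save_config
from .trajectory import Trajectory

__all__ = ["write_trajectory", "read_trajectory", "trajectory_frame"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Long-format per-step table: step, individual, age, x[, p], payoff."""
    steps, N = traj.x.shape
    step_col = np.repeat(np.arange(steps), N)
    ind_col = np.tile(np.arange(N), steps)
    data = {
        "step": step_col,
        "individual": ind_col,
        "age": np.tile(traj.ages, steps),
        "x": traj.x.ravel(),
    }
    if traj.p is not None:
        data["p"] = traj.p.ravel()
    # payoffs exist for completed generations only; final row gets NaN
    pay = np.full((steps, N), np.nan)
    pay[: traj.payoffs.shape[0]] = traj.payoffs
    data["payoff"] = pay.ravel()
    return pd.DataFrame(data)


def write_trajectory(traj: Trajectory, out_dir) -> dict:
    """Write a run to ``out_dir``; returns the manifest (also saved as
    ``manifest.json``) listing every file with its SHA-256 checksum."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    files = []
    tpath = out / "trajectory.csv"
    trajectory_frame(traj).to_csv(tpath, index=False, float_format="%.17g")
    files.append(tpath)

    if traj.stimuli is not None:
        spath = out / "stimuli.csv"
        pd.DataFrame({
            "step": np.arange(traj.stimuli.shape[0]),
            "S0": traj.stimuli[:, 0],
            "S1": traj.stimuli[:, 1],
        }).to_csv(spath, index=False, float_format="%.17g")
        files.append(spath)

    summary = engagement_summary(traj)
    summary["final"] = [float(v) for v in summary["final"]]
    summary["model"] = traj.model
    summary["seed"] = traj.seed
    summary["n_steps"] = traj.n_steps
    jpath = out / "summary.json"
    jpath.write_text(json.dumps(summary, indent=2, sort_keys=True))
    files.append(jpath)

    cpath = out / "config.yaml"
    save_config(RunConfig.from_dict(traj.config), cpath)
    files.append(cpath)

    manifest = {
        "model": traj.model,
        "seed": traj.seed,
        "files": {f.name: _sha256(f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_trajectory(out_dir) -> Trajectory:
    """Reconstruct a :class:`Trajectory` from a run directory written by
    :func:`write_trajectory`."""
    out = Path(out_dir)
    frame = pd.read_csv(out / "trajectory.csv", float_precision="round_trip")
    steps = int(frame["step"].max()) + 1
    N = int(frame["individual"].max()) + 1
    x = frame["x"].to_numpy().reshape(steps, N)
    ages = frame.loc[frame["step"] == 0, "age"].to_numpy()
    pay = frame["payoff"].to_numpy().reshape(steps, N)
    payoffs = pay[~np.isnan(pay).all(axis=1)]
    p = frame["p"].to_numpy().reshape(steps, N) if "p" in frame.columns else None

    stim = None
    spath = out / "stimuli.csv"
    if spath.exists():
        sframe = pd.read_csv(spath, float_precision="round_trip")
        stim = sframe[["S0", "S1"]].to_numpy()

    manifest = json.loads((out / "manifest.json").read_text())
    from .config import load_config
    cfg = load_config(out / "config.yaml")
    return Trajectory(model=manifest["model"], x=x, ages=ages, payoffs=payoffs,
                      p=p, stimuli=stim, config=cfg.to_dict(), seed=manifest["seed"])
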