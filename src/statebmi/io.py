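"""On-disk formats for sessions, trajectories and metric reports.

A spike session is written as three files in a directory:

* ``session.json`` -- metadata and generator parameters;
* ``spikes.csv``   -- columns ``trial, unit, time_s`` (seconds relative to
  stimulus onset; negative = pre-stimulus);
* ``labels.csv``   -- columns ``trial, stimulus``.

Trajectories go to a single CSV with one row per step, metrics to JSON.
All writers are deterministic: identical inputs give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .bmi_sim import Trajectory, TrajectoryMetrics
from .neural_sim import SimParams, SpikeSession, Trial

__all__ = [
    "write_session",
    "read_session",
    "write_trajectories",
    "write_metrics",
]

_TIME_FMT = "%.6f"


def write_session(session: SpikeSession, directory: str | Path) -> Path:
    """Serialize a session to ``session.json`` + ``spikes.csv`` + ``labels.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    meta = {
        "n_units": session.n_units,
        "n_trials": session.n_trials,
        "pre_span_s": session.pre_span,
        "post_span_s": session.post_span,
        "artifact_blank_s": session.artifact_blank,
        "seed": session.seed,
    }
    if session.params is not None:
        params = dataclasses.asdict(session.params)
        params.pop("evoked_templates", None)  # array; regenerated from seed
        meta["params"] = params
    (directory / "session.json").write_text(json.dumps(meta, indent=2) + "\n")

    rows = []
    for trial in session.trials:
        for unit, st in enumerate(trial.spikes):
            for t in st:
                rows.append((trial.index, unit, t))
    spikes = pd.DataFrame(rows, columns=["trial", "unit", "time_s"])
    spikes.to_csv(directory / "spikes.csv", index=False, float_format=_TIME_FMT)

    labels = pd.DataFrame(
        {
            "trial": [t.index for t in session.trials],
            "stimulus": [t.stimulus for t in session.trials],
        }
    )
    labels.to_csv(directory / "labels.csv", index=False)
    return directory


def read_session(directory: str | Path) -> SpikeSession:
    """Load a session written by :func:`write_session`."""
    directory = Path(directory)
    meta = json.loads((directory / "session.json").read_text())
    labels = pd.read_csv(directory / "labels.csv").set_index("trial")["stimulus"]
    spikes = pd.read_csv(directory / "spikes.csv")

    n_units = int(meta["n_units"])
    grouped = {
        (int(t), int(u)): np.sort(g["time_s"].to_numpy())
        for (t, u), g in spikes.groupby(["trial", "unit"])
    }
    trials = []
    for trial_idx, stimulus in labels.sort_index().items():
        per_unit = tuple(
            grouped.get((int(trial_idx), u), np.empty(0)) for u in range(n_units)
        )
        trials.append(
            Trial(index=int(trial_idx), stimulus=int(stimulus), spikes=per_unit)
        )
    params = None
    if "params" in meta:
        raw = dict(meta["params"])
        raw["state_oscillation_band"] = tuple(raw["state_oscillation_band"])
        params = SimParams(**raw)
    return SpikeSession(
        trials=tuple(trials),
        n_units=n_units,
        pre_span=float(meta["pre_span_s"]),
        post_span=float(meta["post_span_s"]),
        artifact_blank=float(meta["artifact_blank_s"]),
        seed=int(meta["seed"]),
        params=params,
    )


def write_trajectories(trajectories: list[Trajectory], path: str | Path) -> Path:
    """Write trajectories as one CSV row per step."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for tid, traj in enumerate(trajectories):
        positions = traj.positions
        for step in range(len(traj.forces)):
            state = traj.states[step + 1]
            rows.append(
                {
                    "trajectory_id": tid,
                    "step": step + 1,
                    "x_cm": state.position[0],
                    "y_cm": state.position[1],
                    "vx": state.velocity[0],
                    "vy": state.velocity[1],
                    "Fx": traj.forces[step][0],
                    "Fy": traj.forces[step][1],
                    "stimulus": traj.stimuli[step],
                    "converged": traj.converged,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")
    return path


def write_metrics(metrics: TrajectoryMetrics, path: str | Path) -> Path:
    """Write a metrics summary as JSON (NaN encoded as null)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "convergence_rate_pct": metrics.convergence_rate,
        "mean_steps": metrics.mean_steps,
        "mean_closest_distance_mm": metrics.mean_closest_distance_mm,
        "mean_f_dir_n": metrics.mean_f_dir,
        "mean_wtv": metrics.mean_wtv,
        "mean_angular_error_deg": metrics.mean_angular_error_deg,
        "n_trajectories": metrics.n_trajectories,
        "per_start_wtv": list(metrics.per_start_wtv),
    }
    cleaned = {
        k: (None if isinstance(v, float) and math.isnan(v) else v)
        for k, v in payload.items()
    }
    path.write_text(json.dumps(cleaned, indent=2) + "\n")
    return path
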