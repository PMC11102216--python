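"""CSV/JSON interchange for the staged pipeline.

File dialects (all plain CSV, one header row; lines starting with ``#`` are
metadata comments):

* participants.csv  — participant_id, group, age, sex, handedness, tlt
* apm_trials.csv    — participant_id, trial, target_x_m, target_y_m,
                      matched_x_m, matched_y_m (matched in the ACTIVE arm's
                      frame; analysis mirrors it into the passive frame)
* trajectories.csv  — participant_id, task, trial, arm, phase, t_s, x_m, y_m
                      (AMM passive/active traces and, optionally, VMR reaches)
* vmr_trials.csv    — participant_id, trial, phase, initial_direction_deg
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import SchemaError
from .kinematics import Trajectory

__all__ = [
    "write_participants",
    "write_apm_trials",
    "write_amm_trajectories",
    "write_vmr_trials",
    "write_cohort",
    "read_apm_trials",
    "read_trajectories",
    "read_vmr_trials",
    "read_csv",
    "write_csv",
]

FLOAT_FORMAT = "%.6g"


def write_csv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a tidy CSV at fixed float precision, with an optional # comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def write_participants(cohort: Cohort, path, header_comment=None) -> None:
    write_csv(cohort.participants_frame(), path, header_comment)


def write_apm_trials(cohort: Cohort, path, header_comment=None) -> None:
    rows = []
    for p in cohort.participants:
        for k, (tgt, mat) in enumerate(zip(p.apm_targets, p.apm_matched)):
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "trial": k,
                    "target_x_m": tgt[0],
                    "target_y_m": tgt[1],
                    "matched_x_m": mat[0],
                    "matched_y_m": mat[1],
                }
            )
    write_csv(pd.DataFrame(rows), path, header_comment)


def _traj_rows(pid, task, trial, arm, phase, traj: Trajectory):
    return pd.DataFrame(
        {
            "participant_id": pid,
            "task": task,
            "trial": trial,
            "arm": arm,
            "phase": phase,
            "t_s": traj.t,
            "x_m": traj.x,
            "y_m": traj.y,
        }
    )


def write_amm_trajectories(cohort: Cohort, path, header_comment=None) -> None:
    frames = []
    for p in cohort.participants:
        for k, (passive, active, failed) in enumerate(p.amm_trials):
            phase = "failed" if failed else "ok"
            frames.append(_traj_rows(p.participant_id, "amm", k, "passive", phase, passive))
            frames.append(_traj_rows(p.participant_id, "amm", k, "active", phase, active))
    write_csv(pd.concat(frames, ignore_index=True), path, header_comment)


def write_vmr_trials(cohort: Cohort, path, header_comment=None) -> None:
    rows = []
    for p in cohort.participants:
        for k, (d, ph) in enumerate(zip(p.vmr.directions, p.vmr.phases)):
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "trial": k,
                    "phase": ph,
                    "initial_direction_deg": d,
                }
            )
    write_csv(pd.DataFrame(rows), path, header_comment)


def write_cohort(cohort: Cohort, outdir, header_comment=None) -> dict:
    """Write the full staged-input bundle for a cohort; returns the file map."""
    outdir = Path(outdir)
    files = {
        "participants": outdir / "participants.csv",
        "apm_trials": outdir / "apm_trials.csv",
        "amm_trajectories": outdir / "amm_trajectories.csv",
        "vmr_trials": outdir / "vmr_trials.csv",
    }
    write_participants(cohort, files["participants"], header_comment)
    write_apm_trials(cohort, files["apm_trials"], header_comment)
    write_amm_trajectories(cohort, files["amm_trajectories"], header_comment)
    write_vmr_trials(cohort, files["vmr_trials"], header_comment)
    return files


def read_apm_trials(path) -> dict:
    """Per-participant (targets, matched) arrays keyed by participant_id."""
    df = read_csv(path)
    _require(df, ["participant_id", "trial", "target_x_m", "target_y_m", "matched_x_m", "matched_y_m"], path)
    out = {}
    for pid, grp in df.groupby("participant_id", sort=False):
        grp = grp.sort_values("trial")
        out[pid] = (
            grp[["target_x_m", "target_y_m"]].to_numpy(),
            grp[["matched_x_m", "matched_y_m"]].to_numpy(),
        )
    return out


def read_trajectories(path) -> dict:
    """Trajectories keyed by (participant_id, task, trial, arm); values
    (Trajectory, phase)."""
    df = read_csv(path)
    _require(df, ["participant_id", "task", "trial", "arm", "phase", "t_s", "x_m", "y_m"], path)
    out = {}
    for key, grp in df.groupby(["participant_id", "task", "trial", "arm"], sort=False):
        grp = grp.sort_values("t_s")
        traj = Trajectory(
            t=grp["t_s"].to_numpy(), x=grp["x_m"].to_numpy(), y=grp["y_m"].to_numpy()
        )
        out[key] = (traj, str(grp["phase"].iloc[0]))
    return out


def read_vmr_trials(path) -> dict:
    """Per-participant (directions, phases) arrays keyed by participant_id."""
    df = read_csv(path)
    _require(df, ["participant_id", "trial", "phase", "initial_direction_deg"], path)
    out = {}
    for pid, grp in df.groupby("participant_id", sort=False):
        grp = grp.sort_values("trial")
        out[pid] = (
            grp["initial_direction_deg"].to_numpy(dtype=float),
            grp["phase"].to_numpy(),
        )
    return out
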