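"""Plain-text I/O for trials, tables and run artifacts.

Every CSV written by the package starts with a ``#``-prefixed metadata line
carrying the config hash and seed, so any output can be traced back to the
exact configuration that produced it; readers skip such lines.
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simulate import GroundTruth, Trial


def write_table(path, df: pd.DataFrame, meta: dict | None = None,
                float_format: str = "%.10g"):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if meta:
            tag = ", ".join(f"{k}={v}" for k, v in meta.items())
            fh.write(f"# {tag}\n")
        df.to_csv(fh, index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"corrupt CSV {path}: {exc}") from exc


def write_trial(trial_dir, trial: Trial, truth: GroundTruth | None = None,
                still: pd.DataFrame | None = None):
    """Write a trial as mocap.csv / imu.csv / baro.csv + trial.json
    (+ groundtruth.csv and still.csv when available)."""
    trial_dir = Path(trial_dir)
    trial_dir.mkdir(parents=True, exist_ok=True)
    tag = {"config_hash": trial.meta.get("config_hash", "n/a"),
           "seed": trial.meta.get("seed", "n/a")}
    write_table(trial_dir / "mocap.csv", trial.mocap, meta=tag)
    write_table(trial_dir / "imu.csv", trial.imu, meta=tag)
    write_table(trial_dir / "baro.csv", trial.baro, meta=tag)
    with open(trial_dir / "trial.json", "w") as fh:
        json.dump(trial.meta, fh, indent=2)
    if truth is not None:
        gt = truth.events.copy()
        gt["clock_offset"] = truth.clock_offset
        write_table(trial_dir / "groundtruth.csv", gt, meta=tag)
    if still is not None:
        write_table(trial_dir / "still.csv", still, meta=tag)


def read_trial(trial_dir) -> Trial:
    trial_dir = Path(trial_dir)
    with open(trial_dir / "trial.json") as fh:
        meta = json.load(fh)
    return Trial(
        mocap=read_table(trial_dir / "mocap.csv"),
        imu=read_table(trial_dir / "imu.csv"),
        baro=read_table(trial_dir / "baro.csv"),
        meta=meta,
    )


def read_groundtruth(trial_dir) -> GroundTruth:
    df = read_table(Path(trial_dir) / "groundtruth.csv")
    offset = float(df["clock_offset"].iloc[0])
    return GroundTruth(events=df.drop(columns=["clock_offset"]),
                       clock_offset=offset)
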