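"""End-to-end orchestration: simulate -> process -> train.

``process_trial`` runs the mocap reference computation and the IMU feature
extraction on one trial and aligns them through the cross-correlation
synchronization; ``process_cohort`` pools trials, applies the ±3 SD outlier
rule once on the pooled table, and hands the dataset to the model suite.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import energetics, features as feat
from .config import SimConfig
from .models import EvalReport, run_model_suite
from .simulate import GroundTruth, Trial, simulate_cohort, simulate_still, cohort_configs

log = logging.getLogger(__name__)

RESPONSE_COLUMNS = ("w_plus", "w_minus", "v_before", "v_after")


def process_trial(trial: Trial, still: pd.DataFrame, window: float = 2.0):
    """Responses, features and synchronization result for one trial.

    Parameters
    ----------
    trial : Trial
        Multi-rate recording (mocap + IMU + barometer).
    still : DataFrame
        Still-unit recording used for static bias estimation.
    window : float
        Analysis window length in seconds (2 s across each turn).

    Returns
    -------
    (responses, features, sync)
        ``responses`` has one row per retained turn (targets + side),
        ``features`` the matching F1..F18 rows, ``sync`` the estimated
        clock lag and per-event detection errors.
    """
    fs_imu = float(trial.meta.get("fs_imu", 512.0))
    fs_mocap = float(trial.meta.get("fs_mocap", 100.0))
    fs_baro = float(trial.meta.get("fs_baro", 64.0))

    bias = feat.estimate_static_bias(still, fs_imu)
    imu_corr = feat.correct_imu(trial.imu, bias, fs_imu)
    imu_events = feat.detect_turns_imu(imu_corr, fs_imu)
    events, responses = energetics.reference_responses(
        trial.mocap, fs_mocap, window=window)
    if responses.empty or imu_events.size == 0:
        raise feat.SynchronizationError("no events detected on one stream")
    sync = feat.synchronize(imu_events, responses["t_star"].to_numpy())
    alt = feat.baro_altitude(trial.baro, fs_baro)

    t_imu = imu_corr["t"].to_numpy()
    gy = imu_corr["gy"].to_numpy()
    rows_f, keep, sides = [], [], []
    for ev, (_, resp) in zip(events, responses.iterrows()):
        t_star_imu = float(resp["t_star"]) + sync.lag
        fv = feat.extract_features(imu_corr, alt, t_star_imu,
                                   fs_imu=fs_imu, window=window)
        side = energetics.turn_side_from_yaw(
            t_imu, gy, energetics.TurnEvent.at(ev.index, t_star_imu, window))
        if fv is None or side is None:
            log.info("turn %d dropped (window truncated or side undetermined)",
                     ev.index)
            continue
        rows_f.append(fv)
        sides.append(side)
        keep.append(resp["turn_id"])
    responses = responses[responses["turn_id"].isin(keep)].reset_index(drop=True)
    responses["side"] = sides
    features_df = pd.DataFrame(rows_f)
    features_df.insert(0, "turn_id", responses["turn_id"].to_numpy())
    log.info("trial processed: %d turns retained, lag %.3f s",
             len(features_df), sync.lag)
    return responses, features_df, sync


def process_cohort(pairs, stills=None, window: float = 2.0,
                   drop_outliers: bool = True):
    """Process a list of (Trial, GroundTruth) pairs into one pooled dataset.

    Returns ``(dataset, syncs, n_outliers)`` where ``dataset`` holds the
    features, responses and subject ids of every retained turn; the ±3 SD
    outlier rule is applied once over the pooled numeric columns.
    """
    frames, syncs = [], []
    for i, item in enumerate(pairs):
        trial = item[0] if isinstance(item, tuple) else item
        if stills is not None:
            still = stills[i]
        else:
            cfg = SimConfig(seed=int(trial.meta.get("seed", 0)))
            still = simulate_still(cfg, duration=120.0)
        responses, features_df, sync = process_trial(trial, still, window=window)
        merged = responses.merge(features_df, on="turn_id")
        merged.insert(0, "subject", i)
        frames.append(merged)
        syncs.append(sync)
    dataset = pd.concat(frames, ignore_index=True)
    n_out = 0
    if drop_outliers and len(dataset) >= 2:
        numeric = [c for c in dataset.columns
                   if c in RESPONSE_COLUMNS or c in feat.FEATURE_NAMES]
        dataset, n_out = feat.remove_outliers(dataset, columns=numeric)
    log.info("cohort: %d turns pooled, %d outliers removed",
             len(dataset) + n_out, n_out)
    return dataset, syncs, n_out


def simulate_processed_cohort(config: SimConfig, n_subjects: int = 13,
                              still_duration: float = 120.0, **kw):
    """Simulate, then process, a cohort; returns (dataset, pairs, syncs)."""
    pairs = simulate_cohort(config, n_subjects)
    stills = [simulate_still(c, duration=still_duration)
              for c in cohort_configs(config, n_subjects)]
    dataset, syncs, n_out = process_cohort(pairs, stills=stills, **kw)
    return dataset, pairs, syncs, n_out


def train_models(dataset: pd.DataFrame, k: int = 10, seed: int = 0,
                 **kw) -> EvalReport:
    """Run the full model suite on a processed pooled dataset."""
    X = dataset[list(feat.FEATURE_NAMES)]
    report = run_model_suite(X, dataset, k=k, seed=seed, **kw)
    report.meta["n_subjects"] = int(dataset["subject"].nunique()) \
        if "subject" in dataset else 1
    return report


def detection_error_sd(syncs) -> float:
    """Pooled SD (s) of matched IMU-vs-mocap event-time differences.

    NaN when fewer than two matched events are available.
    """
    errs = np.concatenate([s.errors for s in syncs])
    if errs.size < 2:
        return float("nan")
    return float(np.std(errs, ddof=1))
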