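"""Reference energetics from the motion-capture centre-of-mass trajectory.

This module computes the regression targets of the analysis: per-turn
positive/negative mass-specific external mechanical work, approach and exit
speed, and (via the vertical-axis angular velocity) the pivot side.  The
external mechanical energy of the centre of mass (CoM) is

    E_ext(t) = 1/2 ||v_CoM(t)||^2 + g h_CoM(t)   [J/kg]

and the positive (negative) external work over the 2 s window across a turn
is the sum of the positive (negative) sample-to-sample increments of E_ext.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filtering import zero_lag_lowpass

log = logging.getLogger(__name__)

G = 9.81  # m/s^2

#: 14-marker set and the body segments defined on it.  Segment masses are
#: the classical cadaver-based fractions (head 8.1%, trunk 49.7%, upper arm
#: 2.8%, forearm 1.6%, hand 0.6%, thigh 10.0%, shank 4.65%, foot 1.45%),
#: which sum to 1 over the whole body.
MARKERS = (
    "tragus_l", "tragus_r", "acromion_l", "acromion_r",
    "olecranon_l", "olecranon_r", "styloid_l", "styloid_r",
    "trochanter_l", "trochanter_r", "epicondyle_l", "epicondyle_r",
    "malleolus_l", "malleolus_r",
)

_SEGMENTS = (
    # (fraction, marker names whose centroid locates the segment)
    (0.081, ("tragus_l", "tragus_r")),
    (0.497, ("acromion_l", "acromion_r", "trochanter_l", "trochanter_r")),
    (0.028, ("acromion_l", "olecranon_l")),
    (0.028, ("acromion_r", "olecranon_r")),
    (0.016, ("olecranon_l", "styloid_l")),
    (0.016, ("olecranon_r", "styloid_r")),
    (0.006, ("styloid_l",)),
    (0.006, ("styloid_r",)),
    (0.100, ("trochanter_l", "epicondyle_l")),
    (0.100, ("trochanter_r", "epicondyle_r")),
    (0.0465, ("epicondyle_l", "malleolus_l")),
    (0.0465, ("epicondyle_r", "malleolus_r")),
    (0.0145, ("malleolus_l",)),
    (0.0145, ("malleolus_r",)),
)


@dataclass
class TurnEvent:
    """A detected 180-degree turn with its 2 s analysis window."""

    index: int
    time: float
    window: tuple

    @classmethod
    def at(cls, index: int, time: float, window: float = 2.0) -> "TurnEvent":
        half = window / 2.0
        return cls(index=index, time=float(time), window=(time - half, time + half))


def filter_com(mocap: pd.DataFrame, fs: float, fc: float = 15.0,
               order: int = 2) -> pd.DataFrame:
    """Zero-lag low-pass the raw CoM (or marker) trajectory columns."""
    out = mocap.copy()
    for col in out.columns:
        if col != "t":
            out[col] = zero_lag_lowpass(out[col].to_numpy(), fs, fc, order)
    return out


def com_velocity(pos: np.ndarray, fs: float) -> np.ndarray:
    """Central-difference velocity of an (n, 3) filtered position array."""
    return np.gradient(np.asarray(pos, dtype=float), 1.0 / fs, axis=0)


def detect_turns_mocap(t, x, min_spacing: float = 1.5) -> np.ndarray:
    """Turn times from the extrema of the CoM position along the lane.

    A 180-degree turn reverses the running direction, so each turn is an
    alternating maximum/minimum of CoM_x.  Extrema closer than
    ``min_spacing`` (step-level wiggles) are rejected.
    """
    from scipy.signal import find_peaks

    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size < 3:
        return np.array([])
    fs = 1.0 / np.median(np.diff(t))
    dist = max(int(round(min_spacing * fs)), 1)
    span = np.ptp(x)
    if span <= 0:
        return np.array([])
    prom = 0.25 * span
    hi, _ = find_peaks(x, distance=dist, prominence=prom)
    lo, _ = find_peaks(-x, distance=dist, prominence=prom)
    idx = np.sort(np.concatenate([hi, lo]))
    return t[idx]


def external_energy(mocap_filtered: pd.DataFrame, fs: float) -> np.ndarray:
    """Mass-specific external mechanical energy series E_ext (J/kg).

    Velocity is obtained by central differences of the already-filtered
    trajectory; height is the vertical coordinate of the CoM.
    """
    pos = mocap_filtered[["x", "y", "z"]].to_numpy()
    v = com_velocity(pos, fs)
    speed = np.linalg.norm(v, axis=1)
    return 0.5 * speed**2 + G * pos[:, 2]


def _window_slice(t: np.ndarray, lo: float, hi: float):
    i0, i1 = np.searchsorted(t, [lo, hi])
    return i0, i1


def turn_work(e_ext: np.ndarray, t: np.ndarray, event: TurnEvent):
    """Positive and negative external work (J/kg) over the event window.

    Returns ``None`` (with a logged warning) when the 2 s window is
    truncated by the recording bounds.  The negative work is returned as a
    magnitude.
    """
    lo, hi = event.window
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        log.warning("turn %d at %.2f s: window truncated, event dropped",
                    event.index, event.time)
        return None
    i0, i1 = _window_slice(t, lo, hi)
    de = np.diff(e_ext[i0:i1])
    w_plus = float(np.sum(np.clip(de, 0.0, None)))
    w_minus = float(abs(np.sum(np.clip(de, None, 0.0))))
    return w_plus, w_minus


def turn_speeds(speed: np.ndarray, t: np.ndarray, event: TurnEvent):
    """Mean CoM speed over the second before and the second after the turn."""
    if event.time - 1.0 < t[0] - 1e-9 or event.time + 1.0 > t[-1] + 1e-9:
        log.warning("turn %d at %.2f s: 1 s margin missing, event dropped",
                    event.index, event.time)
        return None
    i0, ic = _window_slice(t, event.time - 1.0, event.time)
    _, i1 = _window_slice(t, event.time, event.time + 1.0)
    return float(np.mean(speed[i0:ic + 1])), float(np.mean(speed[ic:i1 + 1]))


def turn_side_from_yaw(t_gyro, gy, event: TurnEvent,
                       min_net_deg: float = 45.0):
    """Pivot side from the net vertical-axis rotation over the window.

    In the sensor frame (y up) a positive net yaw rotation is a left turn.
    Returns ``None`` when the net rotation magnitude is below
    ``min_net_deg`` (side undetermined).
    """
    t_gyro = np.asarray(t_gyro, dtype=float)
    gy = np.asarray(gy, dtype=float)
    i0, i1 = _window_slice(t_gyro, event.window[0], event.window[1])
    if i1 - i0 < 2:
        return None
    net = np.trapezoid(gy[i0:i1], t_gyro[i0:i1])
    if abs(net) < min_net_deg:
        return None
    return "left" if net > 0 else "right"


def com_from_markers(markers: pd.DataFrame) -> pd.DataFrame:
    """Whole-body CoM from the 14-marker set by the segmental centroid method.

    Each segment is located at the centroid of its defining markers and the
    CoM is the segment-mass-fraction weighted mean; the fractions sum to 1.
    Raises ``KeyError`` naming the first missing marker.
    """
    for name in MARKERS:
        if f"{name}_x" not in markers.columns:
            raise KeyError(f"missing marker: {name}")
    n = len(markers)
    com = np.zeros((n, 3))
    for frac, names in _SEGMENTS:
        centroid = np.zeros((n, 3))
        for m in names:
            centroid += markers[[f"{m}_x", f"{m}_y", f"{m}_z"]].to_numpy()
        com += frac * centroid / len(names)
    out = pd.DataFrame(com, columns=["x", "y", "z"])
    if "t" in markers.columns:
        out.insert(0, "t", markers["t"].to_numpy())
    return out


def reference_responses(mocap: pd.DataFrame, fs: float, window: float = 2.0,
                        fc: float = 15.0, min_spacing: float = 1.5):
    """Full mocap-side reference computation for one trial.

    Filters the trajectory, detects turn events, and computes W+, W-,
    v_before and v_after per retained event (events whose window is
    truncated by the recording bounds are dropped).

    Returns
    -------
    (events, responses) : (list of TurnEvent, DataFrame)
        One responses row per retained event, without the side label (the
        side comes from the synchronized gyroscope).
    """
    filt = filter_com(mocap, fs, fc=fc)
    times = detect_turns_mocap(filt["t"].to_numpy(), filt["x"].to_numpy(),
                               min_spacing=min_spacing)
    pos = filt[["x", "y", "z"]].to_numpy()
    v = com_velocity(pos, fs)
    speed = np.linalg.norm(v, axis=1)
    e = 0.5 * speed**2 + G * pos[:, 2]
    t = filt["t"].to_numpy()

    events, rows = [], []
    for i, t_star in enumerate(times):
        ev = TurnEvent.at(i, t_star, window)
        work = turn_work(e, t, ev)
        speeds = turn_speeds(speed, t, ev)
        if work is None or speeds is None:
            continue
        events.append(ev)
        rows.append(
            {
                "turn_id": i,
                "t_star": float(t_star),
                "w_plus": work[0],
                "w_minus": work[1],
                "v_before": speeds[0],
                "v_after": speeds[1],
            }
        )
    log.info("mocap reference: %d events detected, %d retained",
             len(times), len(rows))
    return events, pd.DataFrame(rows)
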