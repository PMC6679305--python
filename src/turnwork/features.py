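"""IMU-side processing: bias removal, turn detection, synchronization and
the 18 per-turn predictors.

Feature catalogue (canonical numbering used throughout the package):

====  =========================================================  ========
id    description                                                units
====  =========================================================  ========
F1    player load: sum of norms of consecutive acc differences   A.U.
F2-4  trapezoidal integral of positive acc, axes x/y/z           m/s
F5-7  trapezoidal integral of negative acc, axes x/y/z           m/s
F8    RMS of the acceleration norm                               m/s^2
F9    skewness of the acceleration norm                          --
F10   kurtosis of the acceleration norm                          --
F11-13 trapezoidal integral of angular velocity, axes x/y/z      rad
F14   RMS of the angular-velocity norm                           rad/s
F15   skewness of the angular-velocity norm                      --
F16   kurtosis of the angular-velocity norm                      --
F17   barometric altitude at the turn minus 1 s before           m
F18   barometric altitude 1 s after minus at the turn            m
====  =========================================================  ========

All windows are 2 s across the synchronized turn event.  Skewness and
kurtosis are population moments, E(x - x̄)^3 / sigma^3 and
E(x - x̄)^4 / sigma^4 (no excess-kurtosis correction).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .filtering import zero_lag_lowpass
from .simulate import G, altitude_from_pressure

log = logging.getLogger(__name__)

FEATURE_NAMES = tuple(f"F{i}" for i in range(1, 19))

ACC_CHANNELS = ("ax", "ay", "az")
GYRO_CHANNELS = ("gx", "gy", "gz")


class SynchronizationError(RuntimeError):
    """Cross-correlation between the event streams found no credible lag."""


@dataclass
class SyncResult:
    """Estimated IMU-minus-mocap clock lag and per-event detection errors."""

    lag: float
    peak_correlation: float
    errors: np.ndarray = field(default_factory=lambda: np.array([]))
    n_matched: int = 0

    def to_dict(self) -> dict:
        return {
            "lag": float(self.lag),
            "peak_correlation": float(self.peak_correlation),
            "n_matched": int(self.n_matched),
            "errors": [float(e) for e in self.errors],
        }


def estimate_static_bias(still: pd.DataFrame, fs: float,
                         min_duration: float = 60.0) -> pd.Series:
    """Per-channel static biases from a still-unit recording.

    The bias is the channel mean; on the vertical accelerometer axis (y,
    pointing up while the unit rests) gravity is subtracted first, so that
    removing the returned biases leaves zero-mean channels.
    """
    duration = len(still) / fs
    if duration < min_duration:
        raise ValueError(
            f"still recording of {duration:.0f} s is shorter than the "
            f"required {min_duration:.0f} s"
        )
    bias = still[list(ACC_CHANNELS + GYRO_CHANNELS)].mean()
    bias["ay"] -= G
    return bias


def correct_imu(imu: pd.DataFrame, bias: pd.Series, fs: float,
                fc: float = 128.0, order: int = 4) -> pd.DataFrame:
    """Subtract static biases and apply the zero-lag low-pass pre-filter."""
    out = imu.copy()
    for ch in ACC_CHANNELS + GYRO_CHANNELS:
        out[ch] = zero_lag_lowpass(
            imu[ch].to_numpy() - float(bias[ch]), fs, fc, order)
    return out


def detect_turns_imu(imu: pd.DataFrame, fs: float, fc: float = 0.5,
                     min_spacing: float = 1.5,
                     min_height: float = 30.0) -> np.ndarray:
    """Turn event times (IMU clock) from the smoothed vertical-axis gyro.

    The bias-corrected angular velocity about the vertical (y) axis is
    zero-lag low-passed at ``fc`` and the peaks of its absolute value above
    ``min_height`` (deg/s) and separated by ``min_spacing`` are the turns.
    """
    gy = zero_lag_lowpass(imu["gy"].to_numpy(), fs, fc, order=2)
    dist = max(int(round(min_spacing * fs)), 1)
    idx, _ = sps.find_peaks(np.abs(gy), height=min_height, distance=dist)
    return imu["t"].to_numpy()[idx]


def synchronize(imu_events, mocap_events, fs_common: float = 100.0,
                sigma: float = 0.05, max_lag: float = 3.0,
                min_peak: float = 0.2, match_tol: float = 0.5) -> SyncResult:
    """Clock lag between the IMU and mocap event streams.

    Gaussian-smoothed unit-impulse trains are built at each system's
    candidate event times on a common grid and cross-correlated; the lag of
    maximum normalized cross-correlation (within ``+-max_lag``) estimates
    the IMU-minus-mocap clock offset.  Events are then matched pairwise and
    the residual per-event detection errors reported.
    """
    imu_events = np.sort(np.asarray(imu_events, dtype=float))
    mocap_events = np.sort(np.asarray(mocap_events, dtype=float))
    if imu_events.size == 0 or mocap_events.size == 0:
        raise SynchronizationError("empty event set")

    t0 = min(imu_events[0], mocap_events[0]) - max_lag - 1.0
    t1 = max(imu_events[-1], mocap_events[-1]) + max_lag + 1.0
    n = int(np.ceil((t1 - t0) * fs_common)) + 1
    grid = t0 + np.arange(n) / fs_common

    def train(events):
        a = np.zeros(n)
        idx = np.clip(np.round((events - t0) * fs_common).astype(int), 0, n - 1)
        np.add.at(a, idx, 1.0)
        width = max(int(round(4 * sigma * fs_common)), 1)
        k = np.arange(-width, width + 1) / fs_common
        kernel = np.exp(-0.5 * (k / sigma) ** 2)
        return np.convolve(a, kernel, mode="same")

    a_imu, a_mo = train(imu_events), train(mocap_events)
    corr = sps.correlate(a_imu, a_mo, mode="full")
    lags = sps.correlation_lags(n, n, mode="full") / fs_common
    norm = np.sqrt(np.sum(a_imu**2) * np.sum(a_mo**2))
    corr = corr / norm if norm > 0 else corr
    ok = np.abs(lags) <= max_lag
    best = np.argmax(corr[ok])
    lag = float(lags[ok][best])
    peak = float(corr[ok][best])
    if peak < min_peak:
        raise SynchronizationError(
            f"peak cross-correlation {peak:.3f} below threshold {min_peak}")

    def match(current_lag):
        shifted = imu_events - current_lag
        out = []
        for tm in mocap_events:
            j = np.argmin(np.abs(shifted - tm))
            if abs(shifted[j] - tm) <= match_tol:
                out.append(shifted[j] - tm)
        return np.asarray(out)

    # refine the grid-quantized lag with the mean matched-event residual
    errors = match(lag)
    if errors.size:
        lag = lag + float(np.mean(errors))
        errors = match(lag)
    return SyncResult(lag=lag, peak_correlation=peak,
                      errors=errors, n_matched=len(errors))


def player_load(acc: np.ndarray, n_expected: int | None = None) -> float:
    """Sum of Euclidean norms of consecutive 3-axis acceleration differences."""
    acc = np.asarray(acc, dtype=float)
    if acc.ndim != 2 or acc.shape[1] != 3:
        raise ValueError("acc must be an (n, 3) window")
    if n_expected is not None and acc.shape[0] != n_expected:
        raise ValueError(
            f"window of {acc.shape[0]} samples, expected {n_expected}")
    return float(np.sum(np.linalg.norm(np.diff(acc, axis=0), axis=1)))


def signed_integrals(x: np.ndarray, dt: float):
    """Trapezoidal integrals of the positive and the negative part of x."""
    x = np.asarray(x, dtype=float)
    pos = float(np.trapezoid(np.clip(x, 0.0, None), dx=dt))
    neg = float(np.trapezoid(np.clip(x, None, 0.0), dx=dt))
    return pos, neg


def moment_stats(x: np.ndarray):
    """RMS, population skewness and population kurtosis of a window."""
    x = np.asarray(x, dtype=float)
    rms = float(np.sqrt(np.mean(x**2)))
    sd = float(np.std(x))  # population (divide by n)
    if sd == 0.0:
        raise ValueError("constant window: skewness/kurtosis undefined")
    c = x - np.mean(x)
    skew = float(np.mean(c**3) / sd**3)
    kurt = float(np.mean(c**4) / sd**4)
    return rms, skew, kurt


def baro_altitude(baro: pd.DataFrame, fs: float, fc: float = 1.0,
                  order: int = 10) -> pd.DataFrame:
    """Mean-sea-level altitude from the filtered barometric pressure.

    The pressure series is converted through the international barometric
    formula and smoothed with a zero-lag tenth-order low-pass at 1 Hz.
    """
    h = altitude_from_pressure(baro["p"].to_numpy())
    return pd.DataFrame(
        {"t": baro["t"].to_numpy(), "h": zero_lag_lowpass(h, fs, fc, order)})


def baro_deltas(alt: pd.DataFrame, t_star: float):
    """Altitude drop into the turn (F17) and rise out of it (F18).

    F17 = h(t*) - h(t* - 1 s); F18 = h(t* + 1 s) - h(t*).  A centred dip
    of depth d gives F17 ~ -d and F18 ~ +d.  Returns ``None`` when the 1 s
    margins are unavailable.
    """
    t = alt["t"].to_numpy()
    h = alt["h"].to_numpy()
    if t_star - 1.0 < t[0] - 1e-9 or t_star + 1.0 > t[-1] + 1e-9:
        return None
    i_pre = int(np.argmin(np.abs(t - (t_star - 1.0))))
    i_0 = int(np.argmin(np.abs(t - t_star)))
    i_post = int(np.argmin(np.abs(t - (t_star + 1.0))))
    return float(h[i_0] - h[i_pre]), float(h[i_post] - h[i_0])


def extract_features(imu_corrected: pd.DataFrame, alt: pd.DataFrame,
                     t_star: float, fs_imu: float = 512.0,
                     window: float = 2.0):
    """Assemble the 18 predictors over the 2 s window at the (synchronized)
    IMU-clock event time ``t_star``.

    ``imu_corrected`` must already be bias-corrected and pre-filtered
    (see :func:`correct_imu`); ``alt`` is the filtered altitude series from
    :func:`baro_altitude`.  Returns ``None`` when any window is truncated.
    """
    t = imu_corrected["t"].to_numpy()
    n_win = int(round(window * fs_imu))
    c = int(round((t_star - t[0]) * fs_imu))
    lo, hi = c - n_win // 2, c + n_win // 2
    if lo < 0 or hi > len(t):
        return None

    acc = imu_corrected[list(ACC_CHANNELS)].to_numpy()[lo:hi]
    gyr = np.radians(imu_corrected[list(GYRO_CHANNELS)].to_numpy()[lo:hi])
    dt = 1.0 / fs_imu

    f = {"F1": player_load(acc, n_expected=n_win)}
    pos, neg = zip(*(signed_integrals(acc[:, j], dt) for j in range(3)))
    f["F2"], f["F3"], f["F4"] = pos
    f["F5"], f["F6"], f["F7"] = neg
    rms, skew, kurt = moment_stats(np.linalg.norm(acc, axis=1))
    f["F8"], f["F9"], f["F10"] = rms, skew, kurt
    f["F11"], f["F12"], f["F13"] = (
        float(np.trapezoid(gyr[:, j], dx=dt)) for j in range(3))
    rms, skew, kurt = moment_stats(np.linalg.norm(gyr, axis=1))
    f["F14"], f["F15"], f["F16"] = rms, skew, kurt

    deltas = baro_deltas(alt, t_star)
    if deltas is None:
        return None
    f["F17"], f["F18"] = deltas
    return f


def remove_outliers(dataset: pd.DataFrame, columns=None):
    """Drop rows with any value outside its column mean ± 3 SD.

    Means and SDs are computed once on the full dataset (single pass, no
    iteration).  Non-numeric columns are ignored.
    """
    if len(dataset) < 2:
        raise ValueError("need at least 2 rows")
    if columns is None:
        columns = dataset.select_dtypes(include=[np.number]).columns
    sub = dataset[list(columns)]
    mu, sd = sub.mean(), sub.std(ddof=0)
    ok = ((sub - mu).abs() <= 3.0 * sd + 1e-12).all(axis=1)
    removed = int((~ok).sum())
    log.info("outlier removal: %d of %d rows dropped", removed, len(dataset))
    return dataset.loc[ok].reset_index(drop=True), removed


def coefficient_of_variation(column, na_threshold: float = 50.0) -> float:
    """SD over absolute mean; NaN ("n.a.") for zero-mean or CV beyond the
    threshold, as happens on bimodal variables."""
    x = np.asarray(column, dtype=float)
    mu = np.mean(x)
    if mu == 0.0:
        return float("nan")
    cv = float(np.std(x, ddof=1) / abs(mu))
    return float("nan") if cv > na_threshold else cv
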