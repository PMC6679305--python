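"""Synthetic shuttle-run generator with piecewise-analytic ground truth.

The generator emulates a 5 m shuttle-run protocol: straight constant-speed
legs joined by raised-cosine velocity reversals (180-degree turns), a
raised-cosine vertical centre-of-mass dip around each turn, a step-frequency
vertical bounce on the legs, and a pelvis-mounted six-axis IMU plus
barometer observing the motion through its own clock.  Because every
kinematic profile is piecewise analytic, per-turn speeds and external work
have closed-form ground truth, evaluated on a fine grid independent of the
measurement pipeline.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig

G = 9.81
#: international barometric formula constants (standard atmosphere)
P0 = 101325.0
H_SCALE = 44330.0
H_EXP = 0.1903

GT_FS = 2048.0  # fine grid used for closed-form ground-truth integrals


def pressure_from_altitude(h):
    """Pressure (Pa) at mean-sea-level altitude ``h`` (m), standard atmosphere.

    Uses the international barometric formula ``h = 44330 (1 - (p/p0)^0.1903)``
    inverted for pressure; valid in the troposphere (h < 11 km).
    """
    h = np.asarray(h, dtype=float)
    if np.any(h >= H_SCALE):
        raise ValueError("altitude outside troposphere validity range")
    return P0 * (1.0 - h / H_SCALE) ** (1.0 / H_EXP)


def altitude_from_pressure(p):
    """Mean-sea-level altitude (m) from ambient pressure (Pa)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("pressure must be positive")
    return H_SCALE * (1.0 - (p / P0) ** H_EXP)


@dataclass
class Trial:
    """Multi-rate recording of one shuttle-run trial.

    ``mocap`` columns: t, x, y, z (lab frame, x = running direction,
    z = vertical, 100 Hz, mocap clock).  ``imu`` columns: t, ax, ay, az
    (m/s^2), gx, gy, gz (deg/s) in the sensor frame (x backward, y up,
    z left; IMU clock).  ``baro`` columns: t, p (Pa, IMU clock).
    """

    mocap: pd.DataFrame
    imu: pd.DataFrame
    baro: pd.DataFrame
    meta: dict = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Per-turn generating truth: event times (mocap clock), sides and the
    closed-form responses, plus the IMU-minus-mocap clock offset."""

    events: pd.DataFrame  # t_star, side, v_before, v_after, w_plus, w_minus
    clock_offset: float


class ShuttleProfile:
    """Piecewise-analytic CoM trajectory and pelvis yaw for one trial.

    All methods accept arbitrary (vectorised) absolute times, including
    times before the nominal start, which lets the IMU stream be sampled
    through a shifted clock without edge effects.
    """

    def __init__(self, cfg: SimConfig, sides: np.ndarray):
        self.cfg = cfg
        self.sides = np.asarray(sides, dtype=float)
        n = cfg.n_turns
        T_h = cfg.lane_length / cfg.avg_speed
        T_t = cfg.turn_duration
        # leg speed such that apex-to-apex distance equals the lane length
        self.v_leg = cfg.lane_length / (T_h - T_t * (1.0 - 2.0 / np.pi))
        self.T_h, self.T_t, self.T_d = T_h, T_t, cfg.dip_duration
        self.turn_times = cfg.lead_time + T_t / 2.0 + T_h * np.arange(n)
        self.duration = self.turn_times[-1] + T_t / 2.0 + cfg.tail_time
        self.apex_x = np.where(np.arange(n) % 2 == 0, cfg.lane_length, 0.0)
        self.d_in = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        # cumulative yaw before each turn (rad)
        self.yaw_base = np.pi * np.concatenate([[0.0], np.cumsum(self.sides)[:-1]])

    # -- helpers ---------------------------------------------------------
    def _nearest(self, tau):
        tau = np.atleast_1d(np.asarray(tau, dtype=float))
        k = np.clip(np.searchsorted(self.turn_times, tau), 0, len(self.turn_times) - 1)
        k = np.where(
            (k > 0)
            & (np.abs(tau - self.turn_times[k - 1]) < np.abs(tau - self.turn_times[k])),
            k - 1,
            k,
        )
        return tau, k, tau - self.turn_times[k]

    # -- horizontal motion ----------------------------------------------
    def com_x(self, tau):
        tau, k, u = self._nearest(tau)
        v, T_t = self.v_leg, self.T_t
        edge = self.apex_x[k] - self.d_in[k] * v * T_t / np.pi
        in_turn = np.abs(u) <= T_t / 2.0
        x_turn = self.apex_x[k] - self.d_in[k] * v * (T_t / np.pi) * (
            1.0 - np.cos(np.pi * u / T_t)
        )
        x_leg = edge - self.d_in[k] * v * (np.abs(u) - T_t / 2.0)
        return np.where(in_turn, x_turn, x_leg)

    def vel_x(self, tau):
        tau, k, u = self._nearest(tau)
        v, T_t = self.v_leg, self.T_t
        in_turn = np.abs(u) <= T_t / 2.0
        v_turn = -self.d_in[k] * v * np.sin(np.pi * u / T_t)
        v_leg = -self.d_in[k] * v * np.sign(u)
        return np.where(in_turn, v_turn, v_leg)

    def acc_x(self, tau):
        tau, k, u = self._nearest(tau)
        v, T_t = self.v_leg, self.T_t
        in_turn = np.abs(u) <= T_t / 2.0
        a_turn = -self.d_in[k] * v * (np.pi / T_t) * np.cos(np.pi * u / T_t)
        return np.where(in_turn, a_turn, 0.0)

    # -- vertical motion -------------------------------------------------
    def _dip_terms(self, u):
        """Raised-cosine dip shape s(u) and derivatives (0 outside window)."""
        T_d = self.T_d
        inside = np.abs(u) <= T_d / 2.0
        w = 2.0 * np.pi / T_d
        s = np.where(inside, 0.5 * (1.0 + np.cos(w * u)), 0.0)
        s1 = np.where(inside, -0.5 * w * np.sin(w * u), 0.0)
        s2 = np.where(inside, -0.5 * w * w * np.cos(w * u), 0.0)
        return s, s1, s2

    def step_gate(self, tau):
        """Smooth gate that suppresses stepping around each turn apex."""
        tau, k, u = self._nearest(tau)
        s, _, _ = self._dip_terms(u)
        return 1.0 - s

    def com_z(self, tau):
        cfg = self.cfg
        tau, k, u = self._nearest(tau)
        s, _, _ = self._dip_terms(u)
        w = 2.0 * np.pi * cfg.step_frequency
        return (
            cfg.com_height
            - cfg.vertical_dip_depth * s
            + cfg.step_amplitude * (1.0 - s) * np.sin(w * tau)
        )

    def vel_z(self, tau):
        cfg = self.cfg
        tau, k, u = self._nearest(tau)
        s, s1, _ = self._dip_terms(u)
        w = 2.0 * np.pi * cfg.step_frequency
        g, g1 = 1.0 - s, -s1
        return (
            -cfg.vertical_dip_depth * s1
            + cfg.step_amplitude * (g1 * np.sin(w * tau) + g * w * np.cos(w * tau))
        )

    def acc_z(self, tau):
        cfg = self.cfg
        tau, k, u = self._nearest(tau)
        s, s1, s2 = self._dip_terms(u)
        w = 2.0 * np.pi * cfg.step_frequency
        g, g1, g2 = 1.0 - s, -s1, -s2
        sw, cw = np.sin(w * tau), np.cos(w * tau)
        return (
            -cfg.vertical_dip_depth * s2
            + cfg.step_amplitude * (g2 * sw + 2.0 * g1 * w * cw - g * w * w * sw)
        )

    # -- orientation -----------------------------------------------------
    def yaw(self, tau):
        tau, k, u = self._nearest(tau)
        T_t = self.T_t
        r = np.clip((u + T_t / 2.0) / T_t, 0.0, 1.0)
        phase = r - np.sin(2.0 * np.pi * r) / (2.0 * np.pi)
        return self.yaw_base[k] + self.sides[k] * np.pi * phase

    def yaw_rate(self, tau):
        tau, k, u = self._nearest(tau)
        T_t = self.T_t
        inside = np.abs(u) <= T_t / 2.0
        r = (u + T_t / 2.0) / T_t
        rate = self.sides[k] * (np.pi / T_t) * (1.0 - np.cos(2.0 * np.pi * r))
        return np.where(inside, rate, 0.0)

    # -- derived ---------------------------------------------------------
    def speed(self, tau):
        return np.hypot(self.vel_x(tau), self.vel_z(tau))

    def e_ext(self, tau):
        """Mass-specific external mechanical energy (J/kg)."""
        return 0.5 * self.speed(tau) ** 2 + G * self.com_z(tau)


def _draw_sides(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.direction_policy == "alternating":
        return np.where(np.arange(cfg.n_turns) % 2 == 0, 1.0, -1.0)
    return np.where(rng.random(cfg.n_turns) < cfg.p_left, 1.0, -1.0)


def _ground_truth(profile: ShuttleProfile, clock_offset: float) -> GroundTruth:
    """Closed-form responses from the generating profile on a fine grid."""
    rows = []
    for i, t_star in enumerate(profile.turn_times):
        n = int(GT_FS)
        t_pre = t_star - 1.0 + np.arange(n + 1) / GT_FS
        t_post = t_star + np.arange(n + 1) / GT_FS
        v_before = float(np.mean(profile.speed(t_pre)))
        v_after = float(np.mean(profile.speed(t_post)))
        t_win = t_star - 1.0 + np.arange(2 * n + 1) / GT_FS
        de = np.diff(profile.e_ext(t_win))
        rows.append(
            {
                "turn_id": i,
                "t_star": float(t_star),
                "side": "left" if profile.sides[i] > 0 else "right",
                "v_before": v_before,
                "v_after": v_after,
                "w_plus": float(np.sum(np.clip(de, 0.0, None))),
                "w_minus": float(abs(np.sum(np.clip(de, None, 0.0)))),
            }
        )
    return GroundTruth(events=pd.DataFrame(rows), clock_offset=float(clock_offset))


def _impact_train(cfg: SimConfig, profile: ShuttleProfile, tau: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Gaussian-windowed vertical foot-strike transients (sensor y axis)."""
    if cfg.impact_amplitude <= 0:
        return np.zeros_like(tau)
    t0, t1 = float(tau[0]) - 0.5, float(tau[-1]) + 0.5
    strikes = np.arange(t0, t1, 1.0 / cfg.step_frequency)
    amps = cfg.impact_amplitude * profile.step_gate(strikes)
    amps = amps * rng.uniform(0.7, 1.3, size=strikes.size)
    out = np.zeros_like(tau)
    dt = tau[1] - tau[0]
    half = int(np.ceil(4.0 * cfg.impact_width / dt))
    for ts, amp in zip(strikes, amps):
        if amp <= 0:
            continue
        c = int(round((ts - tau[0]) / dt))
        lo, hi = max(c - half, 0), min(c + half + 1, tau.size)
        if lo >= hi:
            continue
        out[lo:hi] += amp * np.exp(
            -0.5 * ((tau[lo:hi] - ts) / cfg.impact_width) ** 2
        )
    return out


def simulate_trial(config: SimConfig, sides: np.ndarray | None = None):
    """Generate one shuttle-run trial and its ground truth.

    Parameters
    ----------
    config : SimConfig
    sides : array-like of ±1, optional
        Explicit per-turn pivot sides (+1 left, -1 right) overriding the
        direction policy; used e.g. to build mirrored trial pairs.

    Returns
    -------
    (Trial, GroundTruth)
        Multi-rate mocap/IMU/barometer streams and the per-turn generating
        truth.  The same config (same seed) returns bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    drawn = _draw_sides(cfg, rng)
    if sides is None:
        sides = drawn
    else:
        sides = np.asarray(sides, dtype=float)
        if sides.shape != (cfg.n_turns,):
            raise ValueError("sides must have one entry per turn")
    profile = ShuttleProfile(cfg, sides)
    if cfg.clock_offset is None:
        offset = float(rng.uniform(-cfg.clock_offset_range, cfg.clock_offset_range))
    else:
        offset = float(cfg.clock_offset)

    # mocap stream (mocap clock == absolute time)
    n_mo = int(round(profile.duration * cfg.fs_mocap))
    t_mo = np.arange(n_mo) / cfg.fs_mocap
    mocap = pd.DataFrame(
        {
            "t": t_mo,
            "x": profile.com_x(t_mo),
            "y": np.zeros(n_mo),
            "z": profile.com_z(t_mo),
        }
    )

    # IMU stream (IMU clock = absolute + offset, so absolute = t_imu - offset)
    n_imu = int(round(profile.duration * cfg.fs_imu))
    t_imu = np.arange(n_imu) / cfg.fs_imu
    tau = t_imu - offset
    psi = profile.yaw(tau)
    ax_lab = profile.acc_x(tau)
    az_lab = profile.acc_z(tau)
    f_y = az_lab + G + _impact_train(cfg, profile, tau, rng)
    acc = np.column_stack(
        [-np.cos(psi) * ax_lab, f_y, -np.sin(psi) * ax_lab]
    )
    gate = profile.step_gate(tau)
    w_step = 2.0 * np.pi * cfg.step_frequency
    gyro = np.column_stack(
        [
            cfg.roll_amplitude * gate * np.sin(w_step * tau + 1.3),
            np.degrees(profile.yaw_rate(tau)),
            cfg.pitch_amplitude * gate * np.sin(w_step * tau + 0.7),
        ]
    )
    acc += np.asarray(cfg.acc_bias)[None, :]
    gyro += np.asarray(cfg.gyro_bias)[None, :]
    gyro += cfg.gyro_drift_rate * (t_imu / 60.0)[:, None]
    if cfg.acc_noise_sd > 0:
        acc += rng.normal(0.0, cfg.acc_noise_sd, acc.shape)
    if cfg.gyro_noise_sd > 0:
        gyro += rng.normal(0.0, cfg.gyro_noise_sd, gyro.shape)
    acc = np.clip(acc, -16.0 * G, 16.0 * G)
    gyro = np.clip(gyro, -2000.0, 2000.0)
    imu = pd.DataFrame(
        {
            "t": t_imu,
            "ax": acc[:, 0],
            "ay": acc[:, 1],
            "az": acc[:, 2],
            "gx": gyro[:, 0],
            "gy": gyro[:, 1],
            "gz": gyro[:, 2],
        }
    )

    # barometer (shares the IMU clock)
    n_b = int(round(profile.duration * cfg.fs_baro))
    t_b = np.arange(n_b) / cfg.fs_baro
    alt = cfg.site_altitude + profile.com_z(t_b - offset)
    if cfg.baro_noise_sd > 0:
        alt = alt + rng.normal(0.0, cfg.baro_noise_sd, n_b)
    baro = pd.DataFrame({"t": t_b, "p": pressure_from_altitude(alt)})

    meta = {
        "mass": cfg.mass,
        "height": cfg.height,
        "fs_mocap": cfg.fs_mocap,
        "fs_imu": cfg.fs_imu,
        "fs_baro": cfg.fs_baro,
        "site_altitude": cfg.site_altitude,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "duration": float(profile.duration),
    }
    return Trial(mocap=mocap, imu=imu, baro=baro, meta=meta), _ground_truth(
        profile, offset
    )


def simulate_still(config: SimConfig, duration: float = 1800.0) -> pd.DataFrame:
    """Still-unit recording used to estimate static channel biases.

    The unit rests with its y axis up, so the vertical accelerometer channel
    reads gravity plus bias; all other channels read bias (plus drift on the
    gyroscope) only.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 777_000_001)
    n = int(round(duration * cfg.fs_imu))
    t = np.arange(n) / cfg.fs_imu
    acc = np.tile(np.asarray(cfg.acc_bias) + np.array([0.0, G, 0.0]), (n, 1))
    gyro = np.tile(np.asarray(cfg.gyro_bias, dtype=float), (n, 1))
    gyro += cfg.gyro_drift_rate * (t / 60.0)[:, None]
    if cfg.acc_noise_sd > 0:
        acc = acc + rng.normal(0.0, cfg.acc_noise_sd, acc.shape)
    if cfg.gyro_noise_sd > 0:
        gyro = gyro + rng.normal(0.0, cfg.gyro_noise_sd, gyro.shape)
    return pd.DataFrame(
        {
            "t": t,
            "ax": acc[:, 0],
            "ay": acc[:, 1],
            "az": acc[:, 2],
            "gx": gyro[:, 0],
            "gy": gyro[:, 1],
            "gz": gyro[:, 2],
        }
    )


def cohort_configs(config: SimConfig, n_subjects: int) -> list[SimConfig]:
    """Deterministically derive per-subject configs from a master config.

    Subject-level parameters (pace, anthropometrics, dip depth, step
    frequency and amplitudes) are jittered around the cohort means; each
    subject receives an independent sub-seed derived from the master seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    master = np.random.SeedSequence(config.seed)
    kids = master.spawn(n_subjects + 1)
    jit = np.random.default_rng(kids[0])
    configs = []
    for i in range(n_subjects):
        sub_seed = int(kids[i + 1].generate_state(1)[0] & 0x7FFFFFFF)
        configs.append(
            config.replace(
                avg_speed=float(np.clip(jit.normal(config.avg_speed, 0.2), 1.5, 4.0)),
                mass=float(np.clip(jit.normal(config.mass, 7.3), 40.0, 90.0)),
                height=float(np.clip(jit.normal(config.height, 0.05), 1.4, 2.0)),
                vertical_dip_depth=float(
                    np.clip(jit.normal(config.vertical_dip_depth, 0.05), 0.15, 0.8)
                ),
                step_frequency=float(
                    np.clip(jit.normal(config.step_frequency, 0.2), 2.0, 4.0)
                ),
                step_amplitude=float(
                    config.step_amplitude * np.clip(jit.normal(1.0, 0.15), 0.5, 1.5)
                ),
                impact_amplitude=float(
                    config.impact_amplitude * np.clip(jit.normal(1.0, 0.2), 0.4, 1.6)
                ),
                seed=sub_seed,
            )
        )
    return configs


def simulate_cohort(config: SimConfig, n_subjects: int):
    """Generate ``n_subjects`` independent trials with per-subject jitter."""
    return [simulate_trial(c) for c in cohort_configs(config, n_subjects)]


def mirror_trial(trial: Trial, truth: GroundTruth | None = None):
    """Left/right mirror of a trial (lab y -> -y).

    In the stated sensor frame this negates the lateral accelerometer axis
    (z, pointing left) and the roll/yaw gyroscope axes (x backward, y up);
    the pitch axis and the remaining accelerometer channels are invariant.
    """
    imu = trial.imu.copy()
    imu["az"] = -imu["az"]
    imu["gx"] = -imu["gx"]
    imu["gy"] = -imu["gy"]
    mocap = trial.mocap.copy()
    mocap["y"] = -mocap["y"]
    out = Trial(mocap=mocap, imu=imu, baro=trial.baro.copy(), meta=dict(trial.meta))
    if truth is None:
        return out
    ev = truth.events.copy()
    ev["side"] = ev["side"].map({"left": "right", "right": "left"})
    return out, GroundTruth(events=ev, clock_offset=truth.clock_offset)
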