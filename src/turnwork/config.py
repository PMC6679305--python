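"""Simulation and run configuration objects."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


@dataclass
class SimConfig:
    """Parameters of the synthetic 5 m shuttle-run generator.

    The defaults are calibrated so that a noiseless cohort reproduces the
    per-turn response statistics of an elite-level shuttle-run protocol:
    mean approach speed ~2.6 m/s, mean mass-specific positive external work
    ~8.5 J/kg, and a barometric altitude dip of ~0.4 m around each turn.

    Parameters
    ----------
    lane_length : float
        Shuttle lane length in metres (turn lines are at 0 and ``lane_length``).
    avg_speed : float
        Average shuttle pace in m/s, i.e. ``lane_length`` divided by the time
        between consecutive turn apexes.  The constant speed held on the
        straight legs is derived from it and is slightly higher, because part
        of each half-lap is spent in the turnaround blend.
    n_turns : int
        Number of 180-degree turns in the trial.
    step_frequency : float
        Running step frequency in Hz; drives the vertical centre-of-mass
        bounce, the pelvic roll/pitch oscillation and foot-strike transients.
    vertical_dip_depth : float
        Depth in metres of the centre-of-mass lowering around each turn.
    dip_duration : float
        Duration in seconds of the raised-cosine vertical dip (must stay
        below the half-lap period so consecutive dips do not overlap).
    turn_duration : float
        Duration in seconds of the raised-cosine velocity reversal and of the
        180-degree pelvis rotation.
    direction_policy : str
        ``"alternating"`` (left, right, left, ...) or ``"random"`` (each side
        drawn i.i.d. with ``p_left``).
    p_left : float
        Probability of a left turn under the random policy.
    step_amplitude : float
        Amplitude in metres of the step-frequency vertical CoM oscillation.
    impact_amplitude : float
        Peak amplitude in m/s^2 of the Gaussian-windowed foot-strike
        transients added to the vertical accelerometer channel (soft-tissue
        impact content that the CoM trajectory does not contain).
    impact_width : float
        Gaussian sigma in seconds of one foot-strike transient.
    roll_amplitude, pitch_amplitude : float
        Amplitudes in deg/s of step-frequency pelvic angular-velocity
        oscillations about the sensor x (backward) and z (left) axes.
    acc_noise_sd, gyro_noise_sd, baro_noise_sd : float
        White measurement noise; accelerometer in m/s^2, gyroscope in deg/s,
        barometer expressed as metres of altitude equivalent.
    acc_bias, gyro_bias : tuple of float
        Static per-axis biases (m/s^2 and deg/s) added to the IMU channels.
    gyro_drift_rate : float
        Slow linear gyroscope drift in deg/s per minute, identical on the
        three axes.
    clock_offset : float or None
        IMU clock minus mocap clock, in seconds.  ``None`` draws a value
        uniformly in ``+-clock_offset_range`` so the synchronization stage is
        always exercised.
    site_altitude : float
        Mean-sea-level altitude of the floor in metres (barometer baseline).
    com_height : float
        Standing CoM height above the floor in metres.
    mass, height : float
        Subject anthropometrics stored in the trial metadata (never encoded
        in the signals).
    fs_mocap, fs_imu, fs_baro : float
        Nominal sampling rates (Hz) of the three streams.
    seed : int
        Seed of the trial's random generator; the same seed reproduces a
        bit-identical trial.
    """

    lane_length: float = 5.0
    avg_speed: float = 2.55
    n_turns: int = 72
    step_frequency: float = 3.0
    vertical_dip_depth: float = 0.4
    dip_duration: float = 1.4
    turn_duration: float = 0.5
    direction_policy: str = "alternating"
    p_left: float = 0.5
    step_amplitude: float = 0.016
    impact_amplitude: float = 20.0
    impact_width: float = 0.008
    roll_amplitude: float = 25.0
    pitch_amplitude: float = 18.0
    acc_noise_sd: float = 0.05
    gyro_noise_sd: float = 1.0
    baro_noise_sd: float = 0.10
    acc_bias: tuple = (0.06, -0.04, 0.05)
    gyro_bias: tuple = (0.6, -0.4, 0.3)
    gyro_drift_rate: float = 0.1
    clock_offset: float | None = None
    clock_offset_range: float = 2.0
    site_altitude: float = 100.0
    com_height: float = 1.0
    mass: float = 59.0
    height: float = 1.66
    lead_time: float = 3.5
    tail_time: float = 3.5
    fs_mocap: float = 100.0
    fs_imu: float = 512.0
    fs_baro: float = 64.0
    seed: int = 0

    def __post_init__(self):
        if self.lane_length <= 0:
            raise ValueError("lane_length must be positive")
        if self.avg_speed <= 0:
            raise ValueError("avg_speed must be positive")
        if self.n_turns < 1:
            raise ValueError("n_turns must be >= 1")
        for name in ("acc_noise_sd", "gyro_noise_sd", "baro_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.direction_policy not in ("alternating", "random"):
            raise ValueError("direction_policy must be 'alternating' or 'random'")
        half_lap = self.lane_length / self.avg_speed
        if self.turn_duration >= half_lap:
            raise ValueError(
                "turn_duration must be shorter than the lane traversal time "
                f"({half_lap:.2f} s): consecutive turns would overlap"
            )
        if self.dip_duration >= half_lap:
            raise ValueError("dip_duration must be shorter than the half-lap period")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunConfig:
    """End-to-end orchestration settings for the command-line workflow."""

    out_dir: str = "runs"
    n_subjects: int = 13
    sim: SimConfig = field(default_factory=SimConfig)
    window: float = 2.0
    k_folds: int = 10
    seed: int = 0
    regression_families: tuple = (
        "multilinear", "svr_gaussian", "boosted_trees", "ann")
    classifier_families: tuple = ("lda", "svm_gaussian", "boosted_trees", "ann")

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(
            {**dataclasses.asdict(self)}, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
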