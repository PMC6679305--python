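"""IMU feature engineering: biases, detection, sync and the 18 predictors."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from turnwork import (SimConfig, SynchronizationError, baro_deltas,
                      coefficient_of_variation, detect_turns_imu,
                      estimate_static_bias, extract_features, mirror_trial,
                      moment_stats, player_load, remove_outliers,
                      signed_integrals, simulate_still, simulate_trial,
                      synchronize)
from turnwork.features import FEATURE_NAMES, baro_altitude, correct_imu

finite = st.floats(min_value=-50, max_value=50, allow_nan=False)


# ---------------------------------------------------------------- biases
def test_constant_offsets_recovered_exactly():
    cfg = SimConfig(seed=0, acc_noise_sd=0.0, gyro_noise_sd=0.0,
                    gyro_drift_rate=0.0, acc_bias=(0.3, -0.2, 0.1),
                    gyro_bias=(1.5, -2.5, 0.5))
    still = simulate_still(cfg, duration=70.0)
    bias = estimate_static_bias(still, 512.0)
    np.testing.assert_allclose(
        bias[["ax", "ay", "az"]], [0.3, -0.2, 0.1], atol=1e-9)
    np.testing.assert_allclose(
        bias[["gx", "gy", "gz"]], [1.5, -2.5, 0.5], atol=1e-9)


def test_noisy_bias_within_standard_error_and_idempotent():
    cfg = SimConfig(seed=4, gyro_drift_rate=0.0)
    still = simulate_still(cfg, duration=120.0)
    bias = estimate_static_bias(still, 512.0)
    n = len(still)
    for ch, true, sd in (("ax", 0.06, cfg.acc_noise_sd),
                         ("gy", -0.4, cfg.gyro_noise_sd)):
        assert abs(bias[ch] - true) < 3.0 * sd / np.sqrt(n)
    corrected = still.copy()
    for ch in ("ax", "ay", "az", "gx", "gy", "gz"):
        corrected[ch] -= bias[ch]
    re = estimate_static_bias(corrected, 512.0)
    assert np.max(np.abs(re.to_numpy())) < 1e-9


def test_short_still_recording_rejected():
    cfg = SimConfig(seed=0)
    with pytest.raises(ValueError, match="shorter"):
        estimate_static_bias(simulate_still(cfg, duration=10.0), 512.0)


# --------------------------------------------------------------- detection
def test_zero_angular_velocity_yields_no_events():
    n = 512 * 20
    imu = pd.DataFrame({"t": np.arange(n) / 512.0,
                        **{c: np.zeros(n) for c in
                           ("ax", "ay", "az", "gx", "gy", "gz")}})
    assert detect_turns_imu(imu, 512.0).size == 0


def test_noisy_turns_recovered_within_tolerance(noisy_pair, noisy_still):
    trial, truth = noisy_pair
    bias = estimate_static_bias(noisy_still, 512.0)
    corr = correct_imu(trial.imu, bias, 512.0)
    times = detect_turns_imu(corr, 512.0)
    t_true = truth.events["t_star"].to_numpy()
    assert len(times) == len(t_true)
    assert np.max(np.abs(times - t_true)) < 0.2


# ------------------------------------------------------------------- sync
def test_identical_event_sets_have_zero_lag():
    ev = np.arange(10) * 2.0 + 3.0
    res = synchronize(ev, ev)
    assert res.lag == 0.0
    assert res.n_matched == 10
    np.testing.assert_allclose(res.errors, 0.0, atol=1e-9)


def test_injected_offset_recovered_to_grid_resolution():
    ev = np.arange(20) * 1.96 + 3.0
    res = synchronize(ev + 0.5, ev)
    assert res.lag == pytest.approx(0.5, abs=1.0 / 100.0)


def test_jittered_offsets_recovered_despite_event_noise():
    """With 0.1 s per-event timing jitter the refined lag still averages
    the jitter away (error ~ jitter SD / sqrt(n_events))."""
    errs = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        ev = np.arange(60) * 1.96 + 3.0
        offset = rng.uniform(-2.0, 2.0)
        imu_ev = ev + offset + rng.normal(0.0, 0.1, ev.size)
        res = synchronize(imu_ev, ev)
        errs.append(abs(res.lag - offset))
    assert max(errs) <= 0.04  # ~3 sigma of 0.1 / sqrt(60)
    assert np.mean(errs) <= 0.015


def test_sync_failure_paths():
    with pytest.raises(SynchronizationError):
        synchronize(np.array([]), np.array([1.0]))
    rng = np.random.default_rng(0)
    with pytest.raises(SynchronizationError):
        synchronize(np.sort(rng.uniform(0, 60, 30)),
                    np.sort(rng.uniform(0, 60, 30)), min_peak=0.99)


# ----------------------------------------------------------- feature ops
def test_player_load_elementary_windows():
    assert player_load(np.zeros((100, 3))) == 0.0
    step = np.zeros((10, 3))
    step[5:, 0] = 1.0  # one unit step on one axis
    assert player_load(step) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        player_load(np.zeros((10, 3)), n_expected=1024)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.tuples(finite, finite, finite), min_size=2, max_size=6))
def test_player_load_matches_brute_force(rows):
    acc = np.array(rows)
    expected = 0.0
    for i in range(len(acc) - 1):
        d = acc[i + 1] - acc[i]
        expected += float(np.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2))
    assert player_load(acc) == pytest.approx(expected, rel=1e-12, abs=1e-12)


def test_signed_integrals_elementary():
    x = np.array([1.0, 2.0, 0.5])
    pos, neg = signed_integrals(x, 0.1)
    assert pos == pytest.approx(np.trapezoid(x, dx=0.1)) and neg == 0.0
    odd = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    pos, neg = signed_integrals(odd, 0.5)
    assert pos == pytest.approx(-neg)


@settings(derandomize=True, max_examples=50)
@given(st.lists(finite, min_size=2, max_size=8),
       st.floats(min_value=1e-3, max_value=1.0))
def test_signed_integrals_match_manual_trapezoid(vals, dt):
    x = np.array(vals)
    pos, neg = signed_integrals(x, dt)
    xp, xn = np.maximum(x, 0.0), np.minimum(x, 0.0)
    exp_pos = sum((xp[i] + xp[i + 1]) * dt / 2.0 for i in range(len(x) - 1))
    exp_neg = sum((xn[i] + xn[i + 1]) * dt / 2.0 for i in range(len(x) - 1))
    assert pos == pytest.approx(exp_pos, rel=1e-9, abs=1e-9)
    assert neg == pytest.approx(exp_neg, rel=1e-9, abs=1e-9)


def test_moment_stats_reference_cases():
    rms, skew, kurt = moment_stats(np.array([1.0, -1.0] * 50))
    assert rms == pytest.approx(1.0) and skew == pytest.approx(0.0)
    assert kurt == pytest.approx(1.0)  # two-level distribution
    x = np.random.default_rng(0).normal(size=200_000)
    _, skew, kurt = moment_stats(x)
    assert skew == pytest.approx(0.0, abs=0.05)
    assert kurt == pytest.approx(3.0, abs=0.05)
    with pytest.raises(ValueError):
        moment_stats(np.full(10, 2.0))


@settings(derandomize=True, max_examples=50)
@given(st.lists(finite, min_size=5, max_size=5))
def test_moment_stats_match_direct_sums(vals):
    x = np.array(vals)
    if np.std(x) < 1e-6:
        return
    rms, skew, kurt = moment_stats(x)
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = var ** 0.5
    assert rms == pytest.approx((sum(v * v for v in x) / n) ** 0.5, rel=1e-9)
    assert skew == pytest.approx(
        sum((v - mean) ** 3 for v in x) / n / sd**3, rel=1e-6, abs=1e-6)
    assert kurt == pytest.approx(
        sum((v - mean) ** 4 for v in x) / n / sd**4, rel=1e-6, abs=1e-6)


# ------------------------------------------------------------------- baro
def test_flat_altitude_gives_zero_deltas():
    t = np.arange(0, 10, 1 / 64.0)
    alt = pd.DataFrame({"t": t, "h": np.full_like(t, 100.0)})
    assert baro_deltas(alt, 5.0) == (0.0, 0.0)
    assert baro_deltas(alt, 0.5) is None


def test_generator_dip_appears_in_baro_deltas(quiet_pair, quiet_cfg):
    trial, truth = quiet_pair
    alt = baro_altitude(trial.baro, 64.0)
    ts = truth.events["t_star"].iloc[3]
    f17, f18 = baro_deltas(alt, ts)
    assert f17 == pytest.approx(-quiet_cfg.vertical_dip_depth, abs=0.05)
    assert f18 == pytest.approx(quiet_cfg.vertical_dip_depth, abs=0.05)


# ------------------------------------------------------------- assembly
def test_extract_features_equals_composition_of_sub_ops(noisy_pair,
                                                        noisy_still):
    trial, truth = noisy_pair
    bias = estimate_static_bias(noisy_still, 512.0)
    corr = correct_imu(trial.imu, bias, 512.0)
    alt = baro_altitude(trial.baro, 64.0)
    ts = float(truth.events["t_star"].iloc[4])
    fv = extract_features(corr, alt, ts)
    i = int(round(ts * 512))
    acc = corr[["ax", "ay", "az"]].to_numpy()[i - 512:i + 512]
    gyr = np.radians(corr[["gx", "gy", "gz"]].to_numpy()[i - 512:i + 512])
    dt = 1 / 512.0
    assert fv["F1"] == pytest.approx(player_load(acc))
    for j, (p, q) in enumerate((("F2", "F5"), ("F3", "F6"), ("F4", "F7"))):
        pos, neg = signed_integrals(acc[:, j], dt)
        assert fv[p] == pytest.approx(pos) and fv[q] == pytest.approx(neg)
    rms, skew, kurt = moment_stats(np.linalg.norm(acc, axis=1))
    assert (fv["F8"], fv["F9"], fv["F10"]) == pytest.approx((rms, skew, kurt))
    for j, name in enumerate(("F11", "F12", "F13")):
        assert fv[name] == pytest.approx(np.trapezoid(gyr[:, j], dx=dt))
    rms, skew, kurt = moment_stats(np.linalg.norm(gyr, axis=1))
    assert (fv["F14"], fv["F15"], fv["F16"]) == pytest.approx((rms, skew, kurt))
    assert (fv["F17"], fv["F18"]) == pytest.approx(baro_deltas(alt, ts))


def test_feature_invariants_on_noisy_trial(noisy_pair, noisy_still):
    trial, truth = noisy_pair
    bias = estimate_static_bias(noisy_still, 512.0)
    corr = correct_imu(trial.imu, bias, 512.0)
    alt = baro_altitude(trial.baro, 64.0)
    for ts in truth.events["t_star"]:
        fv = extract_features(corr, alt, float(ts))
        vals = np.array([fv[n] for n in FEATURE_NAMES])
        assert np.all(np.isfinite(vals))
        assert fv["F1"] >= 0 and fv["F8"] >= 0 and fv["F14"] >= 0
        assert fv["F2"] >= 0 and fv["F3"] >= 0 and fv["F4"] >= 0
        assert fv["F5"] <= 0 and fv["F6"] <= 0 and fv["F7"] <= 0
        assert fv["F10"] >= 1.0 and fv["F16"] >= 1.0  # kurtosis bound


def test_mirrored_trial_flips_only_side_dependent_features(quiet_cfg):
    trial, truth = simulate_trial(quiet_cfg)
    mirrored = mirror_trial(trial)
    bias = pd.Series(0.0, index=["ax", "ay", "az", "gx", "gy", "gz"])
    ts = float(truth.events["t_star"].iloc[2])
    fvs = []
    for tr in (trial, mirrored):
        corr = correct_imu(tr.imu, bias, 512.0)
        alt = baro_altitude(tr.baro, 64.0)
        fvs.append(extract_features(corr, alt, ts))
    a, b = fvs
    # mirror flips the roll/yaw gyro integrals and swaps the lateral
    # accelerometer's positive/negative integrals
    assert b["F11"] == pytest.approx(-a["F11"], abs=1e-9)
    assert b["F12"] == pytest.approx(-a["F12"], abs=1e-9)
    assert b["F4"] == pytest.approx(-a["F7"], abs=1e-9)
    assert b["F7"] == pytest.approx(-a["F4"], abs=1e-9)
    for name in ("F1", "F2", "F3", "F5", "F6", "F8", "F9", "F10",
                 "F13", "F14", "F15", "F16", "F17", "F18"):
        assert b[name] == pytest.approx(a[name], rel=1e-9, abs=1e-9)


# ----------------------------------------------------------- outliers, CV
def test_planted_outlier_removed_identical_rows_kept():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
    planted = df["a"].mean() + 5.0 * df["a"].std()
    df.loc[7, "a"] = planted
    kept, n = remove_outliers(df)
    assert n == 1 and planted not in kept["a"].to_numpy()
    twins = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]})
    kept, n = remove_outliers(twins)
    assert n == 0 and len(kept) == 2
    with pytest.raises(ValueError):
        remove_outliers(twins.iloc[:1])


def test_gaussian_outlier_rate_matches_binomial_expectation():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.normal(size=(900, 5)),
                      columns=list("abcde"))
    _, n = remove_outliers(df)
    # P(row beyond 3 sigma in any of 5 cols) ~ 1.3%; 4-sigma binomial band
    assert 2 <= n <= 26


def test_coefficient_of_variation_cases():
    assert coefficient_of_variation(np.full(10, 4.2)) == \
        pytest.approx(0.0, abs=1e-12)
    z = np.array([-1.0, -1.0, 1.0, 1.0])
    x = 8.49 + 2.35 * z / np.std(z, ddof=1)
    assert coefficient_of_variation(x) == pytest.approx(2.35 / 8.49)
    assert np.isnan(coefficient_of_variation(np.array([-1.0, 1.0])))
    rng = np.random.default_rng(2)
    col = rng.normal(10.0, 2.0, 500)
    assert coefficient_of_variation(col) == pytest.approx(
        np.std(col, ddof=1) / abs(np.mean(col)))
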