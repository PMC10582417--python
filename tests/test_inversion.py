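"""Speed/temperature inversion: round trips, oracle equivalence, sensitivity."""

import numpy as np
import pytest

import thermogait as tg
from thermogait.errors import IdentifiabilityError
from thermogait.inversion import estimate_window, solve_speed_shank, solve_speed_thigh
from thermogait.teg import TEGChannelModel, channel_response, default_generator_models


def _exact_features(calib, v, dTs, dTt, fs, ft, Tair=26.0, t_start=0.0):
    return {
        "t_start": t_start, "Tair": Tair, "active": True, "valid": True,
        "Vs1": channel_response(calib["shank_dc"], dTs, v, fs),
        "Vs2": channel_response(calib["shank_ac"], dTs, v, fs),
        "Vt1": channel_response(calib["thigh_dc"], dTt, v, ft),
        "Vt2": channel_response(calib["thigh_ac"], dTt, v, ft),
        "fs": fs, "ft": ft,
    }


@pytest.fixture(scope="module")
def calib():
    return default_generator_models()


def test_noiseless_shank_inversion(calib):
    row = _exact_features(calib, v=5.0, dTs=8.2, dTt=6.8, fs=1.25, ft=1.25)
    assert solve_speed_shank(row["Vs1"], row["Vs2"], row["fs"], calib) == pytest.approx(5.0, abs=1e-4)


def test_noiseless_thigh_inversion(calib):
    row = _exact_features(calib, v=7.0, dTs=8.2, dTt=6.8, fs=1.55, ft=1.55)
    assert solve_speed_thigh(row["Vt1"], row["Vt2"], row["ft"], calib) == pytest.approx(7.0, abs=1e-4)


def test_estimate_window_round_trip(calib):
    row = _exact_features(calib, v=6.0, dTs=8.0, dTt=7.0, fs=1.4, ft=1.4)
    est = estimate_window(row, calib)
    assert est.valid
    assert est.v_hat == pytest.approx(6.0, abs=1e-3)
    assert est.Ts_hat == pytest.approx(26.0 + 8.0, abs=1e-3)
    assert est.Tt_hat == pytest.approx(26.0 + 7.0, abs=1e-3)


def test_air_temperature_additivity(calib):
    """Raising Tair by 1 degC with identical voltages raises both skin
    temperatures by exactly 1 degC."""
    row = _exact_features(calib, v=5.0, dTs=8.0, dTt=7.0, fs=1.25, ft=1.25)
    warm = dict(row, Tair=row["Tair"] + 1.0)
    a, b = estimate_window(row, calib), estimate_window(warm, calib)
    assert b.Ts_hat - a.Ts_hat == pytest.approx(1.0, abs=1e-12)
    assert b.Tt_hat - a.Tt_hat == pytest.approx(1.0, abs=1e-12)
    assert b.v_hat == pytest.approx(a.v_hat, abs=1e-12)


def test_inactive_window_uses_static_inversion(calib):
    dTs, dTt = 8.0, 7.0
    row = {"t_start": 0.0, "Tair": 26.0, "active": False, "valid": True,
           "Vs1": dTs * np.sqrt(calib["shank_dc"].I),
           "Vt1": dTt * np.sqrt(calib["thigh_dc"].I),
           "Vs2": 0.3, "Vt2": 0.3, "fs": 0.0, "ft": 0.0}
    est = estimate_window(row, calib)
    assert est.v_hat == 0.0
    assert est.Ts_hat == pytest.approx(34.0, abs=1e-9)
    assert est.Tt_hat == pytest.approx(33.0, abs=1e-9)


def test_degenerate_model_unidentifiable():
    calib = {
        "shank_dc": TEGChannelModel("shank_dc", 9.0, 0.0, 1, 1),
        "shank_ac": TEGChannelModel("shank_ac", 6.0, 0.0, 2, 1),
    }
    with pytest.raises(IdentifiabilityError):
        solve_speed_shank(40.0, 30.0, 1.2, calib)


def test_invalid_inputs_rejected(calib):
    with pytest.raises(IdentifiabilityError):
        solve_speed_shank(40.0, 0.0, 1.2, calib)
    with pytest.raises(IdentifiabilityError):
        solve_speed_thigh(40.0, 30.0, 0.0, calib)


def _oracle_joint_grid(V1, V2, f, m1, m2, v_step=0.01):
    """Brute-force minimization of the two squared channel residuals over
    a dense speed grid — the independent cross-check of the
    ratio-elimination solver.

    dT enters both residuals linearly, so for each grid speed the exact
    minimizing dT is used (closed-form least squares); discretizing dT as
    well would only blur the v location of the optimum.
    """
    v = np.arange(0.0, 12.0 + v_step / 2, v_step)
    a1 = np.sqrt((m1.I + m1.J * v ** m1.m) / f ** m1.n)
    a2 = np.sqrt((m2.I + m2.J * v ** m2.m) / f ** m2.n)
    dT_best = (a1 * V1 + a2 * V2) / (a1 ** 2 + a2 ** 2)
    resid = (dT_best * a1 - V1) ** 2 + (dT_best * a2 - V2) ** 2
    return v[np.argmin(resid)]


def _n_ratio_roots(V1, V2, f, m1, m2):
    """Count sign changes of the ratio equation over a dense speed grid
    (independent of the solver's polynomial machinery)."""
    lhs = (V1 / V2) ** 2 * f ** (m1.n - m2.n)
    v = np.arange(0.0, 12.0, 0.002)
    g = (m1.I + m1.J * v ** m1.m) / (m2.I + m2.J * v ** m2.m) - lhs
    return int(np.sum(np.diff(np.sign(g)) != 0))


def test_solver_agrees_with_joint_grid_oracle():
    """Ratio elimination matches the 2-D brute-force oracle within one
    grid step on 100 random instances.

    Only uniquely-invertible instances are compared: when the channel
    ratio crosses the measured level twice (possible below its extremum),
    'the' solution is ill-defined for solver and oracle alike, and root
    selection is exercised separately.
    """
    rng = np.random.default_rng(42)
    n_checked = 0
    k = 0
    while n_checked < 100:
        k += 1
        shank = k % 2 == 0
        if shank:
            m1 = TEGChannelModel("shank_dc", rng.uniform(5, 15), rng.uniform(3, 9), 1, 1)
            m2 = TEGChannelModel("shank_ac", rng.uniform(3, 9), rng.uniform(1, 4), 2, 1)
        else:
            m1 = TEGChannelModel("thigh_dc", rng.uniform(5, 15), rng.uniform(3, 9), 1, 1)
            m2 = TEGChannelModel("thigh_ac", rng.uniform(4, 10), rng.uniform(1, 4), 2, 3)
        v_true = rng.uniform(1.5, 9.0)
        dT = rng.uniform(4.0, 10.0)
        f = rng.uniform(0.8, 2.0)
        V1 = channel_response(m1, dT, v_true, f)
        V2 = channel_response(m2, dT, v_true, f)
        if _n_ratio_roots(V1, V2, f, m1, m2) != 1:
            continue
        calib = {m1.channel_id: m1, m2.channel_id: m2}
        if shank:
            v_solver = solve_speed_shank(V1, V2, f, calib)
        else:
            v_solver = solve_speed_thigh(V1, V2, f, calib)
        v_oracle = _oracle_joint_grid(V1, V2, f, m1, m2)
        assert v_solver == pytest.approx(v_oracle, abs=0.0101)
        n_checked += 1


def test_twin_root_selection_follows_continuity(calib):
    """Below the extremum of the shank channel ratio the equation has two
    roots; the solver picks the one nearest the previous estimate, else
    the smallest."""
    m1, m2 = calib["shank_dc"], calib["shank_ac"]
    v_lo = 0.5
    V1 = channel_response(m1, 8.0, v_lo, 1.0)
    V2 = channel_response(m2, 8.0, v_lo, 1.0)
    assert solve_speed_shank(V1, V2, 1.0, calib, prev_v=0.4) == pytest.approx(v_lo, abs=1e-6)
    v_mirror = solve_speed_shank(V1, V2, 1.0, calib, prev_v=2.0)
    assert v_mirror > v_lo
    # default (no history): smallest root
    assert solve_speed_shank(V1, V2, 1.0, calib) == pytest.approx(v_lo, abs=1e-6)


def test_thigh_frequency_sensitivity_matches_finite_difference(calib):
    """A +10% error in ft shifts v_hat as the local derivative predicts
    (the f^2 factor in the thigh ratio makes ft a first-order input)."""
    row = _exact_features(calib, v=5.0, dTs=8.2, dTt=6.8, fs=1.25, ft=1.25)
    v0 = solve_speed_thigh(row["Vt1"], row["Vt2"], 1.25, calib)
    eps = 1e-4
    dv_df = (solve_speed_thigh(row["Vt1"], row["Vt2"], 1.25 + eps, calib) - v0) / eps
    v_pert = solve_speed_thigh(row["Vt1"], row["Vt2"], 1.25 * 1.1, calib)
    predicted = v0 + dv_df * 0.125
    shift = v_pert - v0
    assert shift != 0
    assert v_pert == pytest.approx(predicted, abs=0.2 * abs(shift))


def test_speed_error_shrinks_with_noise():
    """Median absolute window speed error decreases monotonically as the
    voltage noise level drops (20 seeds per level, one session each)."""
    calib = default_generator_models()
    med_errors = []
    for rel_sd in (0.04, 0.02, 0.005):
        errs = []
        for seed in range(20):
            noise = tg.NoiseConfig(voltage_rel_sd=rel_sd, accel_sd=0.05, strain_sd=0.002)
            proto = tg.ProtocolConfig(seed=100 + seed, speeds=(3.0, 5.5, 8.0), dwell=10.0)
            rec = tg.generate_session(proto, noise=noise)
            feats = tg.extract_features(rec)
            est = tg.estimate_session(feats, calib)
            n_per = int(2 * rec.raw_rate)
            for k, row in est.iterrows():
                if row.valid and row.v_hat > 0:
                    v_true = rec.df.iloc[k * n_per:(k + 1) * n_per].v_true.mean()
                    errs.append(abs(row.v_hat - v_true))
        med_errors.append(np.median(errs))
    assert med_errors[0] > med_errors[1] > med_errors[2]
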