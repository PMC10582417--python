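"""End-to-end treadmill workflow: simulate -> calibrate -> decompose ->
invert -> metabolic cross-validation -> fidelity -> power budget.

:func:`run_demo` reproduces the whole monitoring chain on generated
sessions and returns one summary dict of every accuracy and budget figure
the system reports; it is the programmatic face of ``thermogait demo``
and the basis of the acceptance checks.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .calibration import calibrate_all
from .features import extract_features
from .inversion import estimate_session
from .io import write_manifest, write_sessions
from .metabolic import NetConfig, evaluate_loo
from .metrics import fidelity_index, hysteresis_error, mape, rmse
from .power import (ScheduleConfig, default_ledger, average_power, savings,
                    sustainability_check)
from .session import (ProtocolConfig, StrainSensorConfig, generate_sessions,
                      strain_transduce)


def speed_temperature_accuracy(sessions, calib, window: float = 2.0) -> dict:
    """Pooled speed MAPE/RMSE and skin-temperature MAE of the analytic
    inversion against ground truth, over valid active windows."""
    v_hat, v_true, ts_err, tt_err = [], [], [], []
    for rec in sessions:
        feats = extract_features(rec, window=window)
        est = estimate_session(feats, calib)
        n_per = int(round(window * rec.raw_rate))
        for k, row in est.iterrows():
            if not row["valid"] or row["v_hat"] == 0:
                continue
            chunk = rec.df.iloc[k * n_per:(k + 1) * n_per]
            v_hat.append(row["v_hat"])
            v_true.append(chunk["v_true"].mean())
            ts_err.append(abs(row["Ts_hat"] - chunk["Ts_true"].mean()))
            tt_err.append(abs(row["Tt_hat"] - chunk["Tt_true"].mean()))
    return {
        "speed_mape_pct": mape(v_hat, v_true),
        "speed_rmse_kmh": rmse(v_hat, v_true),
        "shank_temp_mae_c": float(np.mean(ts_err)),
        "thigh_temp_mae_c": float(np.mean(tt_err)),
        "n_windows": len(v_hat),
    }


def strain_fidelity(rec) -> dict:
    """Fidelity indices of the strain channel and of one accelerometer
    axis against the ground-truth knee angle."""
    angle = rec.df["knee_angle"].to_numpy()
    return {
        "strain_fidelity": fidelity_index(rec.df["strain"].to_numpy(), angle),
        "accel_fidelity": fidelity_index(rec.df["ax"].to_numpy(), angle),
    }


def strain_hysteresis(cfg: StrainSensorConfig | None = None, n: int = 400) -> float:
    """Hysteresis error (%) of the strain sensor over a full triangular
    0 -> max_strain -> 0 sweep."""
    cfg = cfg or StrainSensorConfig()
    up = np.linspace(0.0, cfg.max_strain, n)
    down = up[::-1]
    out = strain_transduce(np.concatenate([up, down]), cfg)
    return hysteresis_error((up, out[:n]), (down, out[n:]))


def budget_report(schedule: ScheduleConfig | None = None) -> dict:
    """Mode/strategy power totals, ECM savings and sustainability."""
    schedule = schedule or ScheduleConfig()
    led = default_ledger()
    rep = {}
    for mode in ("static", "dynamic"):
        for strat in ("ECM", "RTM"):
            rep[f"power_{mode}_{strat.lower()}_uw"] = average_power(led, mode, strat)
        rep[f"savings_{mode}_pct"] = savings(led, mode)
        sus = sustainability_check(schedule, led, mode=mode, strategy="ECM")
        rep[f"supply_{mode}_uw"] = sus.supply_uw
        rep[f"sustainable_{mode}"] = sus.sustainable
    return rep


def run_demo(seed: int = 0, outdir=None, protocol: ProtocolConfig | None = None,
             net_config: NetConfig | None = None) -> dict:
    """Execute the full pipeline on generated sessions; deterministic per seed.

    Returns a JSON-serializable summary with six report sections: speed,
    temperature, metabolic, fidelity, hysteresis and budget.  With
    ``outdir``, also writes the sessions, summary and manifest there.
    """
    protocol = protocol or ProtocolConfig(seed=seed)
    net_config = net_config or NetConfig(seed=seed)
    sessions = generate_sessions(protocol)

    calib, reports = calibrate_all(sessions)
    inv = speed_temperature_accuracy(sessions, calib)
    met = evaluate_loo(sessions, net_config)
    fid = strain_fidelity(sessions[0])
    hyst = strain_hysteresis()
    budget = budget_report()

    summary = {
        "seed": int(seed),
        "speed": {k: inv[k] for k in ("speed_mape_pct", "speed_rmse_kmh", "n_windows")},
        "temperature": {k: inv[k] for k in ("shank_temp_mae_c", "thigh_temp_mae_c")},
        "metabolic": {"mape_pct": met.pooled_mape, "rmse_wkg": met.pooled_rmse,
                      "per_fold": met.per_fold},
        "fidelity": fid,
        "hysteresis_error_pct": hyst,
        "budget": budget,
        "calibration": {cid: (None if m is None else m.to_dict())
                        for cid, m in calib.items()},
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sessions(sessions, outdir / "sessions")
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
        write_manifest(outdir, seed, {"protocol": asdict(protocol),
                                      "net": asdict(net_config)})
    return summary
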