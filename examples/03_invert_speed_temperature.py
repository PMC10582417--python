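"""Invert the calibrated model: per-window speed and skin temperatures.

Each active 2 s window gives (V1, V2, f) per leg; the DC/AC channel ratio
eliminates the unknown temperature difference and leaves a polynomial in
the speed, whose root is the estimate.  Back-substitution recovers the
skin temperatures.
"""

import logging

import thermogait as tg
from thermogait.pipeline import speed_temperature_accuracy

logging.disable(logging.WARNING)

sessions = tg.generate_sessions(tg.ProtocolConfig(seed=0))
calib = tg.default_calibration()

feats = tg.extract_features(sessions[0])
est = tg.estimate_session(feats, calib)
print("first windows of session 0:")
print(est[["t_start", "v_hat", "Ts_hat", "Tt_hat"]].head(5).round(3).to_string(index=False))

acc = speed_temperature_accuracy(sessions, calib)
print(f"\npooled over {acc['n_windows']} active windows of six sessions:")
print(f"  speed MAPE {acc['speed_mape_pct']:.2f} %   RMSE {acc['speed_rmse_kmh']:.3f} km/h")
print(f"  shank temperature MAE {acc['shank_temp_mae_c']:.3f} degC, "
      f"thigh {acc['thigh_temp_mae_c']:.3f} degC")
# Sub-percent speed error and hundredth-degree temperature error on
# synthetic data: the inversion itself is essentially exact, so on real
# hardware accuracy is limited by sensor noise and model mismatch.
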