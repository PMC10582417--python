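"""Metabolic-rate estimation with the 5-cell LSTM, leave-one-session-out.

Knee strain + tri-axial acceleration are resampled to 5 Hz and windowed
into 10-step sequences; each of the six sessions is held out once while
the network trains on the other five.
"""

import logging

import thermogait as tg

logging.disable(logging.WARNING)

sessions = tg.generate_sessions(tg.ProtocolConfig(seed=0))
cfg = tg.NetConfig(cells=5, input_rate=5.0, window=2.0, seed=0)
X, y, sid = tg.make_dataset(sessions, cfg)
print(f"dataset: {X.shape[0]} windows of {X.shape[1]} steps x {X.shape[2]} channels; "
      f"targets {y.min():.1f}-{y.max():.1f} W/kg")

report = tg.evaluate_loo(sessions, cfg)
for fold in report.per_fold:
    print(f"  fold {fold['fold']}: MAPE {fold['mape']:5.2f} %  RMSE {fold['rmse']:.3f} W/kg")
print(f"pooled: MAPE {report.pooled_mape:.2f} %  RMSE {report.pooled_rmse:.3f} W/kg")
# A few percent MAPE: the tiny recurrent network reads speed (hence
# metabolic load) off the amplitude and cadence of the motion channels.
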