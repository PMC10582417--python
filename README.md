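# thermogait

Edge-computing signal chain of a self-powered, leg-worn health monitor:
flexible thermoelectric generators (TEGs) on the shank and thigh harvest
body heat *and* double as zero-power motion sensors. This package
implements, as a tested library with a small CLI, everything that happens
between the raw sensor channels and the health parameters the device
broadcasts — on fully synthetic treadmill sessions, so every stage is
reproducible without any recorded subject data.

## The science in brief

**Sensing model.** A TEG's output is driven by the skin–air temperature
difference ΔT (Seebeck effect) and modulated by convective cooling from
the air flow that locomotion induces. Extending the classic hot-wire
King's law with the gait frequency *f*, each channel obeys

```
(V / ΔT)² · fⁿ = I + J·vᵐ        (m, n small positive integers)
```

where *V* is the channel output (mV), *v* the locomotion speed (km/h),
and (I, J, m, n) fitted coefficients. Four channels are modelled: the DC
level (V₁) and gait-locked AC amplitude (V₂) of each leg's TEG; the thigh
AC channel carries *f³*, the rest *f*. With the per-leg pair of equations,
the ratio (V₁/V₂)² eliminates ΔT and leaves a polynomial in *v* — solved
exactly per 2 s window — and back-substitution plus Tₛ = T_air + ΔT gives
the skin temperatures.

**Metabolic rate.** A single-layer LSTM with 5 cells reads 2 s windows of
knee strain-gauge signal + tri-axial shank acceleration, resampled to
5 Hz (10 timesteps × 4 channels), and regresses metabolic energy
expenditure (W/kg). It is evaluated by leave-one-session-out
cross-validation with MAPE and RMSE. The LSTM, BPTT and Adam are
implemented in numpy (~200 parameters; seconds to train, bit-reproducible).

**Signal quality.** The *fidelity index* is the peak normalized
cross-correlation between a sensor channel and the ground-truth knee
angle; the *hysteresis error* is the loading/unloading discrepancy of the
strain gauge as a percent of full scale.

**Power budget.** A duty-cycled state machine keeps only the MCU and
accelerometer alive at rest (polling at 0.25 Hz) and switches to 10 Hz
sampling with 0.25 Hz estimate-and-broadcast cycles when activity is
detected. A per-component ledger compares on-board edge computing (ECM)
against raw-data streaming (RTM), and a sustainability check weighs the
demand against harvested power through a 35%-efficient DC-DC boost
converter.

**Synthetic sessions.** The generator emulates the treadmill protocol the
system targets — 3→8 km/h in 1 km/h steps, 30 s per speed, six sessions,
50 Hz — with ground-truth labels for every quantity the pipeline
estimates, plus configurable noise, gait-cadence jitter, strain-gauge
hysteresis and a monotone speed→metabolic-rate map.

## Worked example

```python
import thermogait as tg
from thermogait.pipeline import speed_temperature_accuracy

sessions = tg.generate_sessions(tg.ProtocolConfig(seed=0))
calib, reports = tg.calibrate_all(sessions)
print(calib["thigh_ac"])
# TEGChannelModel(channel_id='thigh_ac', I=7.962714040707129,
#                 J=3.0021414768858166, m=2, n=3)

acc = speed_temperature_accuracy(sessions, calib)
print(round(acc["speed_mape_pct"], 2), round(acc["shank_temp_mae_c"], 3))
# 0.21 0.021
```

The calibration recovers the generator's coefficients (true thigh AC:
I=8, J=3, m=2, n=3) — including the f³ exponent — from noisy windows, and
the inversion then tracks speed with 0.21% MAPE and shank skin
temperature within 0.021 °C on the synthetic fixture. Leave-one-session-out
metabolic estimation on the same six sessions (`tg.evaluate_loo`) pools
to 4.31% MAPE / 0.434 W kg⁻¹ RMSE. The `examples/` scripts walk through
each capability and print these numbers with commentary; the same
pipeline is available from the shell:

```
thermogait demo --seed 0 --out out/
thermogait simulate --sessions 6 --seed 0 --out sessions/
thermogait budget --mode dynamic
```

## Layout

- `src/thermogait/teg.py` — forward King's-law channel model, harvest curve
- `src/thermogait/session.py` — synthetic treadmill-session generator
- `src/thermogait/features.py` — per-window (V₁, V₂, f) decomposition, activity detection
- `src/thermogait/calibration.py` — exponent-grid OLS coefficient fitting
- `src/thermogait/inversion.py` — ratio-elimination speed/temperature solver
- `src/thermogait/metabolic.py` — numpy LSTM, training, leave-one-out evaluation
- `src/thermogait/metrics.py` — fidelity index, hysteresis error, MAPE/RMSE
- `src/thermogait/power.py` — power ledger, mode state machine, sustainability
- `src/thermogait/io.py`, `cli.py`, `pipeline.py` — files, CLI, end-to-end demo

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
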