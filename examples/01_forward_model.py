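"""Forward TEG sensing model: voltage vs temperature difference, speed, gait.

Evaluates one calibrated channel of the King's-law model
V = dT * sqrt((I + J v^m) / f^n) across the treadmill speed range, and the
harvested-power curve the energy budget draws on.
"""

import numpy as np

import thermogait as tg

models = tg.default_generator_models()
shank_dc = models["shank_dc"]
gait = tg.GaitConfig()

print(f"shank DC channel: I={shank_dc.I}, J={shank_dc.J}, m={shank_dc.m}, n={shank_dc.n}")
print("\n v [km/h]   f [Hz]   V [mV]  (dT = 8.2 degC)")
for v in range(3, 9):
    f = float(gait.cadence(v))
    V = tg.channel_response(shank_dc, dT=8.2, v=v, f=f)
    print(f"   {v}       {f:5.2f}   {V:6.1f}")
print("At rest the gait term drops: V =",
      round(tg.static_response(shank_dc, dT=8.2), 1), "mV")
# Voltages stay inside the 20-90 mV span the conditioning electronics expect.

print("\n v [km/h]   harvested power [uW]")
for v in [0, 3, 6, 9]:
    print(f"   {v}        {tg.harvested_power(v):7.0f}")
# 60 uW at rest -> 1600 uW at 9 km/h: faster motion cools the cold side
# harder, raising the thermoelectric output the system can live off.
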