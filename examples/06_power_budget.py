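"""Duty-cycled power budget: can harvested body heat run the monitor?

Compares on-board edge computing (ECM) against raw-data streaming (RTM)
in both activity modes, checks supply vs demand through the 35% DC-DC
boost converter, and traces the mode state machine over an activity bout.
"""

import thermogait as tg
from thermogait.power import average_power, default_ledger, run_state_machine, savings

led = default_ledger()
print("mode     ECM [uW]  RTM [uW]  ECM saving")
for mode in ("static", "dynamic"):
    p_e = average_power(led, mode, "ECM")
    p_r = average_power(led, mode, "RTM")
    print(f"{mode:8s} {p_e:7.1f}  {p_r:8.1f}   {savings(led, mode):5.1f} %")

cfg = tg.ScheduleConfig()
for mode in ("static", "dynamic"):
    rep = tg.sustainability_check(cfg, led, mode=mode)
    print(f"{mode}: supply {rep.supply_uw:.0f} uW vs demand {rep.demand_uw:.1f} uW "
          f"-> {'sustainable' if rep.sustainable else 'NOT sustainable'}")
# 60/300 uW harvested x 35% conversion = 21/105 uW effective — above the
# 8.1/92.1 uW the edge-computing strategy draws, so the monitor is
# energy-autonomous in both modes.

trace = [False] * 5 + [True] * 25   # rest 10 s, then 50 s of walking
tl = run_state_machine(trace, cfg)
switch = [t for t, e in tl.events if e == "enter_dynamic"][0]
first = [t for t, e in tl.events if e == "broadcast"][0]
print(f"\nactivity at 10 s: mode switch at {switch:.0f} s (0.25 Hz poll), "
      f"first broadcast at {first:.0f} s (after 2 s buffer), "
      f"{tl.n_broadcasts} broadcasts total")
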