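"""Power ledger arithmetic, ECM/RTM comparison, mode state machine."""

import numpy as np
import pytest

import thermogait as tg
from thermogait.power import (PowerLedger, ScheduleConfig, average_power,
                              default_ledger, run_state_machine, savings,
                              sustainability_check)


class TestLedger:
    def test_default_ledger_reproduces_measured_mode_totals(self):
        led = default_ledger()
        assert average_power(led, "static", "ECM") == pytest.approx(8.1, abs=1e-9)
        assert average_power(led, "static", "RTM") == pytest.approx(13.9, abs=1e-9)
        assert average_power(led, "dynamic", "ECM") == pytest.approx(92.1, abs=1e-9)
        assert average_power(led, "dynamic", "RTM") == pytest.approx(168.7, abs=1e-9)

    def test_empty_ledger_totals_zero(self):
        assert average_power(PowerLedger(), "static", "ECM") == 0.0

    def test_missing_cell_raises_listing_present(self):
        led = PowerLedger()
        led.add("mcu", "static", "ECM", 5.0)
        with pytest.raises(KeyError, match="static"):
            average_power(led, "dynamic", "RTM")

    def test_savings_match_total_arithmetic(self):
        led = default_ledger()
        assert savings(led, "dynamic") == pytest.approx(100 * (168.7 - 92.1) / 168.7)
        assert savings(led, "static") == pytest.approx(100 * (13.9 - 8.1) / 13.9)
        assert savings(led, "dynamic") > 40.0

    def test_equal_strategies_save_nothing(self):
        led = PowerLedger()
        led.add("mcu", "static", "ECM", 5.0)
        led.add("mcu", "static", "RTM", 5.0)
        assert savings(led, "static") == 0.0

    def test_scaling_ledger_preserves_savings(self):
        led = default_ledger()
        scaled = led.scaled(3.7)
        assert average_power(scaled, "dynamic", "ECM") == pytest.approx(3.7 * 92.1)
        assert savings(scaled, "dynamic") == pytest.approx(savings(led, "dynamic"))

    def test_duty_weighting(self):
        led = PowerLedger()
        led.add("radio", "dynamic", "ECM", 100.0, duty=0.25)
        assert average_power(led, "dynamic", "ECM") == pytest.approx(25.0)

    def test_invalid_duty_rejected(self):
        with pytest.raises(tg.DomainError):
            PowerLedger().add("x", "static", "ECM", 1.0, duty=1.5)


class TestSustainability:
    def test_static_supply_21_uw_sustains_ecm(self):
        rep = sustainability_check(ScheduleConfig(), default_ledger(), mode="static")
        assert rep.supply_uw == pytest.approx(21.0)       # 60 uW x 35%
        assert rep.demand_uw == pytest.approx(8.1)
        assert rep.sustainable

    def test_dynamic_supply_exceeds_105_uw(self):
        rep = sustainability_check(ScheduleConfig(), default_ledger(), mode="dynamic")
        assert rep.supply_uw >= 105.0
        assert rep.sustainable

    def test_boundary_counts_as_sustainable(self):
        led = PowerLedger()
        led.add("mcu", "static", "ECM", 50.0)
        cfg = ScheduleConfig(dcdc_efficiency=1.0)
        rep = sustainability_check(cfg, led, harvest=50.0, mode="static")
        assert rep.sustainable

    def test_efficiency_validation(self):
        with pytest.raises(tg.DomainError):
            ScheduleConfig(dcdc_efficiency=0.0)


class TestStateMachine:
    def test_all_inactive_no_broadcasts(self):
        tl = run_state_machine([False] * 30)
        assert tl.n_broadcasts == 0
        assert all(m == "static" for m in tl.mode)

    def test_60s_active_trace_gives_15_broadcasts(self):
        # 0.25 Hz reporting over 60 s, first event after the 2 s buffer fill
        tl = run_state_machine([True] * 30)
        assert tl.n_broadcasts == 15

    def test_mode_switch_and_buffer_fill_latency(self):
        # activity starts at t = 10 s; polls run every 4 s, so the switch
        # lands at t = 12 s and the first broadcast at 12 + 2 s
        trace = [False] * 5 + [True] * 25
        tl = run_state_machine(trace)
        switches = [t for t, e in tl.events if e == "enter_dynamic"]
        broadcasts = [t for t, e in tl.events if e == "broadcast"]
        assert switches == [12.0]
        assert broadcasts[0] >= 12.0  # never before activity onset + buffer
        assert broadcasts[0] == pytest.approx(14.0)

    def test_return_to_static_stops_broadcasts(self):
        trace = [True] * 10 + [False] * 20
        tl = run_state_machine(trace)
        last_broadcast = max(t for t, e in tl.events if e == "broadcast")
        switch_back = [t for t, e in tl.events if e == "enter_static"][0]
        assert last_broadcast < switch_back

    def test_deterministic(self):
        trace = [True, False] * 15
        a = run_state_machine(trace)
        b = run_state_machine(trace)
        assert a.events == b.events and a.mode == b.mode

    def test_broadcast_count_scales_with_active_duration(self):
        # after buffer fill, events come at the report rate
        for windows in (15, 45, 90):
            tl = run_state_machine([True] * windows)
            duration = windows * 2.0
            # events at t = 2 + 4k for t strictly inside the trace
            expected = int(np.floor((duration - 2.0 - 1e-9) / 4.0)) + 1
            assert tl.n_broadcasts == expected

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            run_state_machine([])
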