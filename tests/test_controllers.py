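"""Ventilation timing, volume-guarantee adaptation, assist triggers, alarms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mevsim.components import PatientSpec, SpecError
from mevsim.controllers import (
    AlarmState,
    AssistConfig,
    CycleMetrics,
    PCVConfig,
    VGConfig,
    assist_detect_expiration,
    assist_detect_inspiration,
    evaluate_alarms,
    pcv_valve_command,
    vg_adapt,
)
from mevsim.sim_engine import vg_closed_loop

hyp = settings(derandomize=True, max_examples=100, deadline=None)


class TestPCVTiming:
    def test_inspiration_window(self):
        # RR 20 -> 3 s cycle; I:E 1:2 -> inspiration during [0, 1) s
        cfg = PCVConfig(respiratory_rate=20.0, ie_ratio=(1, 2))
        assert pcv_valve_command(0.5, cfg) == (True, False)

    def test_expiration_window(self):
        cfg = PCVConfig(respiratory_rate=20.0, ie_ratio=(1, 2))
        assert pcv_valve_command(2.0, cfg) == (False, True)

    @hyp
    @given(t=st.floats(0.0, 100.0))
    def test_periodicity(self, t):
        cfg = PCVConfig(respiratory_rate=20.0, ie_ratio=(1, 2))
        assert pcv_valve_command(t, cfg) == pcv_valve_command(t + cfg.period, cfg)

    @hyp
    @given(t=st.floats(0.0, 100.0), rr=st.floats(14.0, 30.0), off=st.floats(0.0, 3.0))
    def test_counterphase_exclusivity(self, t, rr, off):
        cfg = PCVConfig(respiratory_rate=rr, ie_ratio=(1, 2), phase_offset=off)
        insp, exp = pcv_valve_command(t, cfg)
        assert insp != exp  # exactly one valve open

    def test_duty_range_enforced(self):
        with pytest.raises(SpecError):
            PCVConfig(ie_ratio=(2, 1))  # inspiration longer than expiration
        with pytest.raises(SpecError):
            PCVConfig(ie_ratio=(1, 4))  # shorter than the 1:3 floor
        PCVConfig(ie_ratio=(1, 1))
        PCVConfig(ie_ratio=(1, 3))


class TestVolumeGuarantee:
    def test_on_target_unchanged(self):
        cfg = VGConfig(tidal_target=0.4)
        f, alarm = vg_adapt(0.33, 0.4, cfg, dt=3.0)
        assert f == pytest.approx(0.33)
        assert not alarm

    def test_shortfall_lengthens_inspiration(self):
        cfg = VGConfig(tidal_target=0.4)
        f, alarm = vg_adapt(0.33, 0.3, cfg, dt=3.0)
        assert f > 0.33
        assert alarm

    def test_overshoot_shortens_inspiration(self):
        cfg = VGConfig(tidal_target=0.4)
        f, _ = vg_adapt(0.33, 0.5, cfg, dt=3.0)
        assert f < 0.33

    @hyp
    @given(
        f=st.floats(0.25, 0.5),
        measured=st.floats(0.0, 2.0),
        dt=st.floats(0.5, 10.0),
    )
    def test_never_exits_duty_bounds(self, f, measured, dt):
        cfg = VGConfig(tidal_target=0.4)
        new, _ = vg_adapt(f, measured, cfg, dt=dt)
        assert 0.25 <= new <= 0.5

    def test_closed_loop_reaches_feasible_target(self):
        # R = 12, C = 0.045 lung at PIP 24 with PEEP 8 and RR 30: a 0.4 L
        # target is reachable inside the duty range; the loop must be within
        # 5% of target by t = 90 s and stay inside 1:1..1:3 throughout
        patient = PatientSpec(resistance=12.0, compliance=0.045, peep=8.0)
        pcv = PCVConfig(respiratory_rate=30.0, ie_ratio=(1, 2))
        df = vg_closed_loop(patient, VGConfig(tidal_target=0.4), pcv, duration=100.0)
        assert ((df.inspiratory_fraction >= 0.25) & (df.inspiratory_fraction <= 0.5)).all()
        late = df[df.time_s >= 90.0]
        assert np.all(np.abs(late.measured_tidal_L - 0.4) <= 0.05 * 0.4)
        assert not late.alarm.any()


class TestAssistTriggers:
    def test_flat_pressure_no_trigger(self):
        cfg = AssistConfig(trigger_pressure_drop=2.0)
        assert not assist_detect_inspiration([24.0, 24.0, 24.0], 24.0, cfg)

    def test_threshold_inclusive(self):
        cfg = AssistConfig(trigger_pressure_drop=2.0)
        assert assist_detect_inspiration([24.0, 22.0], 24.0, cfg)

    def test_half_dip_no_trigger(self):
        cfg = AssistConfig(trigger_pressure_drop=2.0)
        assert not assist_detect_inspiration([24.0, 23.0], 24.0, cfg)

    def test_flow_decay_boundary(self):
        cfg = AssistConfig(flow_termination_fraction=0.25, max_inspiration_time=1.5)
        assert assist_detect_expiration(0.25 * 2.0, 2.0, 0.5, cfg)

    def test_timeout_with_high_flow(self):
        cfg = AssistConfig(flow_termination_fraction=0.25, max_inspiration_time=1.5)
        assert assist_detect_expiration(1.9, 2.0, 1.6, cfg)

    def test_no_trigger_above_threshold(self):
        cfg = AssistConfig(flow_termination_fraction=0.25, max_inspiration_time=1.5)
        assert not assist_detect_expiration(0.6, 2.0, 0.5, cfg)


class TestAlarms:
    def test_all_in_range(self):
        m = CycleMetrics(delivered_tidal=0.45, minute_volume=9.0)
        state = evaluate_alarms(m, tidal_range=(0.3, 0.5), minute_volume_target=6.0)
        assert not state.active_alarms

    def test_tidal_out_of_range(self):
        m = CycleMetrics(delivered_tidal=0.2, minute_volume=9.0)
        state = evaluate_alarms(m, tidal_range=(0.3, 0.5), minute_volume_target=6.0)
        assert "tidal_out_of_range" in state.active_alarms

    def test_minute_volume_unmet(self):
        m = CycleMetrics(delivered_tidal=0.4, minute_volume=4.0)
        state = evaluate_alarms(m, tidal_range=(0.3, 0.5), minute_volume_target=6.0)
        assert "minute_volume_unmet" in state.active_alarms

    def test_phase_timeout(self):
        m = CycleMetrics(delivered_tidal=0.4, minute_volume=9.0, inspiration_timed_out=True)
        state = evaluate_alarms(m, tidal_range=(0.3, 0.5), minute_volume_target=6.0)
        assert "phase_timeout" in state.active_alarms

    def test_volume_guarantee_latch_and_clear(self):
        vg = VGConfig(tidal_target=0.5)
        state = AlarmState()
        low = CycleMetrics(delivered_tidal=0.3, minute_volume=9.0)
        state = evaluate_alarms(low, (0.2, 0.6), 6.0, vg=vg, state=state)
        assert "volume_guarantee_unmet" in state.active_alarms
        ok = CycleMetrics(delivered_tidal=0.5, minute_volume=9.0)
        state = evaluate_alarms(ok, (0.2, 0.6), 6.0, vg=vg, state=state)
        assert "volume_guarantee_unmet" not in state.active_alarms
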