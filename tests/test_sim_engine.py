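"""Full-system dynamics: conservation, safety cap, uncoupling, asynchrony."""

from dataclasses import replace

import numpy as np
import pytest

import mevsim.network as net
from mevsim.components import PatientSpec, ValveSpec
from mevsim.design_calc import NOMINAL_MAIN_LINE_VOLUME_L, total_dead_volume
from mevsim.controllers import PCVConfig
from mevsim.network import LayoutSpec, Scenario, build_system, validate_system
from mevsim import sim_engine
from mevsim.sim_engine import run, summarize, worst_case_scenario


def _two_patient_scenario(duration=3.0, **patient_kwargs):
    kwargs = dict(resistance=10.0, compliance=0.05, tidal_target=0.4)
    kwargs.update(patient_kwargs)
    patients = tuple(PatientSpec(**kwargs) for _ in range(2))
    layout = LayoutSpec(patients_per_limb=(2,))
    system = build_system(layout, patients)
    return Scenario(
        system=system,
        patients=net.patients_with_distances(system, patients),
        bjs=sim_engine.BellJarSpec(),
        supply=sim_engine.SupplySpec(),
        controllers=tuple(PCVConfig() for _ in patients),
        duration=duration,
    )


class TestWorstCaseFixture:
    def test_is_valid_and_has_25_m_line(self, wc_scenario):
        assert validate_system(wc_scenario.system) == []
        assert wc_scenario.patients[-1].distance_from_bjs == pytest.approx(25.0)
        assert len(wc_scenario.patients) == 10

    def test_ledger_with_as_specified_components(self, wc_scenario):
        ledger = total_dead_volume(
            wc_scenario.bjs.dead_volume,
            wc_scenario.bjs.dynamic_range_volume,
            NOMINAL_MAIN_LINE_VOLUME_L,
        )
        assert ledger.total == pytest.approx(75.92)

    def test_rc_spread_spans_design_ranges(self, wc_scenario):
        rs = [p.resistance for p in wc_scenario.patients]
        cs = [p.compliance for p in wc_scenario.patients]
        assert min(rs) == 6.0 and max(rs) == 18.0
        assert min(cs) == 0.03 and max(cs) == 0.06


class TestEquilibrium:
    def test_closed_valves_hold_uniform_pip(self):
        # every patient parked in its expiratory phase with the lung already
        # at PEEP equilibrium: nothing moves
        scn = worst_case_scenario(duration=1.5)
        ctrl = tuple(replace(c, phase_offset=-1.0) for c in scn.controllers)
        res = run(replace(scn, controllers=ctrl))
        pip = scn.bjs.pip
        assert np.allclose(res.node_pressures, pip, atol=1e-6)
        assert np.allclose(res.bell_level, 0.0, atol=1e-9)
        assert np.allclose(res.lung_volumes, 0.0, atol=1e-9)


class TestWorstCaseRun:
    def test_all_lungs_reach_target_quickly(self, wc_summary):
        assert max(wc_summary.time_to_target) < 0.75

    def test_farthest_patient_deficit_bounded(self, wc_summary):
        assert wc_summary.volume_deficit_pct[-1] <= 8.0

    def test_bell_drop_within_buffer(self, wc_summary):
        assert abs(wc_summary.min_bell_level) <= 3.5
        assert abs(wc_summary.min_bell_level) < 8.6

    def test_full_tidal_delivered(self, wc_summary):
        assert np.allclose(wc_summary.delivered_tidal, 0.5, atol=1e-6)

    def test_inlet_pressure_dips_and_recovers(self, wc_result, wc_scenario):
        # farthest patient: pressure dips below PIP early in the breath and
        # climbs back toward PIP before the inspiratory window closes
        col = wc_result.node_names.index(wc_result.scenario.system.patient_attachments[-1])
        win = wc_result.time <= 1.0
        p = wc_result.node_pressures[win, col]
        t = wc_result.time[win]
        pip = wc_scenario.bjs.pip
        i_min = int(np.argmin(p))
        assert p[i_min] < pip - 0.5
        assert t[i_min] < 0.3
        assert p[-1] > p[i_min] + 0.5 * (pip - p[i_min])

    def test_mass_conservation(self, wc_summary):
        assert abs(wc_summary.mass_balance_residual) < 1e-6

    def test_pressure_cap(self, wc_result, wc_scenario):
        cap = wc_scenario.bjs.pip + wc_scenario.bjs.escape_margin
        assert wc_result.node_pressures.max() <= cap + 0.01

    def test_deterministic(self, wc_scenario, wc_result):
        again = run(wc_scenario)
        assert np.array_equal(again.time, wc_result.time)
        assert np.array_equal(again.lung_volumes, wc_result.lung_volumes)

    def test_event_log_records_cycle(self, wc_result):
        labels = [lbl for _, lbl in wc_result.events]
        assert any("inspiration start" in l for l in labels)
        assert any("tidal target reached" in l for l in labels)


class TestUncoupling:
    def test_perturbing_one_patient_leaves_others_unchanged(self, wc_scenario, wc_summary):
        pats = list(wc_scenario.patients)
        pats[4] = replace(pats[4], tidal_target=0.3)
        pert = summarize(run(replace(wc_scenario, patients=tuple(pats))))
        for k in range(10):
            if k == 4:
                continue
            change = abs(pert.delivered_tidal[k] - wc_summary.delivered_tidal[k])
            assert 100.0 * change / wc_summary.delivered_tidal[k] < 2.0

    def test_more_patients_deepen_bell_excursion(self):
        mins = [
            abs(summarize(run(worst_case_scenario(n_patients=n))).min_bell_level)
            for n in (2, 5, 10)
        ]
        assert mins[0] <= mins[1] <= mins[2]

    def test_more_patients_depress_inlet_pressure(self):
        p1 = [
            summarize(run(worst_case_scenario(n_patients=n))).min_inlet_pressure[0]
            for n in (2, 10)
        ]
        assert p1[1] <= p1[0]

    def test_asynchrony_relieves_the_bell(self, wc_scenario, wc_summary):
        ctrl = tuple(
            replace(c, phase_offset=0.3 * k) for k, c in enumerate(wc_scenario.controllers)
        )
        staggered = summarize(run(replace(wc_scenario, controllers=ctrl,
                                          synchronous_start=False)))
        assert abs(staggered.min_bell_level) < abs(wc_summary.min_bell_level)


class TestSummaries:
    def test_identical_patients_have_zero_mutual_deficit(self):
        s = summarize(run(_two_patient_scenario()))
        assert s.volume_deficit_pct[1] == pytest.approx(0.0, abs=0.5)

    def test_zero_duration_is_degenerate_not_fatal(self):
        s = summarize(run(_two_patient_scenario(duration=0.0)))
        assert s.degenerate
        assert np.isnan(s.min_bell_level)

    def test_frame_has_stable_columns(self, wc_result):
        df = wc_result.to_frame()
        assert df.shape[0] == wc_result.time.size
        for col in ("time_s", "bell_level_cm", "q_supply_L_s", "cum_supply_L",
                    "v_lung_p0_L", "p_limb0/module9_cmH2O"):
            assert col in df.columns
        assert np.all(np.diff(df.time_s.to_numpy()) > 0)


class TestModelVariants:
    def test_second_order_bell(self):
        res = run(worst_case_scenario(), bell_model="second_order")
        s = summarize(res)
        assert abs(s.mass_balance_residual) < 1e-6
        assert abs(s.min_bell_level) < 8.6
        # while the bell floats back up the regulator overshoots and the
        # water seal spills the excess: pressure is capped near PIP + margin
        cap = res.scenario.bjs.pip + res.scenario.bjs.escape_margin
        assert res.node_pressures.max() <= cap + 1.0
        assert s.total_vented_volume > 0.0
        assert any("relief vent open" in lbl for _, lbl in res.events)

    def test_second_order_bell_holds_equilibrium(self):
        scn = worst_case_scenario(duration=1.0)
        ctrl = tuple(replace(c, phase_offset=-1.0) for c in scn.controllers)
        res = run(replace(scn, controllers=ctrl), bell_model="second_order")
        assert np.allclose(res.node_pressures, scn.bjs.pip, atol=1e-6)
        assert np.allclose(res.bell_level, 0.0, atol=1e-6)

    def test_inertance_deepens_the_transient_dip(self, wc_summary):
        scn = worst_case_scenario()
        edges = tuple(
            replace(e, pipe=replace(e.pipe, inertance_enabled=True)) if e.pipe else e
            for e in scn.system.edges
        )
        scn_i = replace(scn, system=replace(scn.system, edges=edges))
        s = summarize(run(scn_i))
        assert s.min_inlet_pressure[-1] < wc_summary.min_inlet_pressure[-1]
        assert abs(s.mass_balance_residual) < 1e-6
        assert max(s.time_to_target) < 0.75  # dips are brief; delivery unaffected

    def test_invalid_system_refused(self):
        scn = _two_patient_scenario()
        broken = replace(
            scn, system=replace(scn.system,
                                edges=tuple(e for e in scn.system.edges if e.kind != "relief"))
        )
        with pytest.raises(net.ConfigurationError):
            run(broken)
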