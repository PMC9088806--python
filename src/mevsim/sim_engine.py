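"""Dynamic simulation of the full ventilator network.

The system is integrated as a lumped pneumatic network: gas-storage nodes
(the 2" line, one node per 2.2 m patient module plus a lead node per limb)
with polytropic compressibility linearised around the operating point
(dP/dV = gamma * p_abs / V per node), connected by friction pipe runs
(laminar term plus a constant-friction-factor quadratic term, optional
inertance), Kv switch valves in series with each patient's linear R-C lung,
and a water-sealed bell jar as the pressure source.

Bell models
-----------
``quasi_static`` (default): the bell weight is instantaneously balanced by
gas pressure, so the bell-jar node holds PIP exactly and the level is a pure
volume integrator fed by the supply servo.  ``second_order``: the bell is a
damped mass riding on the compressible head space; the head-space pressure
becomes a state and the water-seal relief vent acts on it directly.  No
manufacturer inertia/friction data exist, so the second-order variant uses a
0.7 damping ratio against the gas-spring stiffness and is offered for
sensitivity studies only.

Stiffness: the line nodes are stiff (a 4.5 L node at ~1 atm absolute has
dP/dV ~ 330 cmH2O/L) against near-zero pipe friction, so the integrator is
BDF with terminal events for the volume-guarantee valve cut-offs; phase
switches of the ventilation cycle are handled as exact segment boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .components import (
    BAR_PER_CMH2O,
    BellJarSpec,
    GasProperties,
    PatientSpec,
    PipeSpec,
    SupplySpec,
    ValveSpec,
)
from .controllers import PCVConfig, pcv_valve_command, vg_adapt, VGConfig
from .network import (
    BJS_NODE,
    ConfigurationError,
    LayoutSpec,
    Scenario,
    SystemModel,
    build_system,
    validate_system,
)

__all__ = [
    "SolverOptions",
    "SystemState",
    "SimulationResult",
    "SummaryMetrics",
    "run",
    "worst_case_scenario",
    "summarize",
    "single_lung_response",
    "vg_closed_loop",
    "SolverError",
]

PA_PER_CMH2O = 98.0665
MU_GAS = 1.81e-5  # Pa s, air-like dynamic viscosity
F_TURB = 0.03  # constant Darcy friction factor for the quadratic term
VENT_CONDUCTANCE = 5.0  # L/s per cmH2O of excess at the water seal
BELL_OVERFLOW_CONDUCTANCE = 10.0  # 1/s, quasi-static bell-top spill rate


class SolverError(RuntimeError):
    """Integration failed; carries the last valid state for diagnosis."""

    def __init__(self, message: str, t: float, y: np.ndarray):
        super().__init__(f"{message} (at t = {t:.6f} s)")
        self.t = t
        self.last_state = y


@dataclass(frozen=True)
class SolverOptions:
    method: str = "BDF"
    rtol: float = 1e-6
    atol: float = 1e-8
    output_dt: float = 1e-3
    max_step: float = math.inf


@dataclass(frozen=True)
class SystemState:
    """Snapshot of the full system at one instant."""

    t: float
    node_pressures: np.ndarray  # cmH2O gauge, one per main-line node
    lung_volumes: np.ndarray  # L, one per patient
    bell_level: float  # cm relative to set-point
    insp_open: np.ndarray  # bool per patient
    exp_open: np.ndarray
    vented_volume: float  # L cumulative


@dataclass
class SimulationResult:
    """Time-aligned trajectories of one run plus the event log."""

    time: np.ndarray
    node_names: tuple[str, ...]
    node_pressures: np.ndarray  # (n_samples, n_nodes)
    lung_volumes: np.ndarray  # (n_samples, n_patients)
    bell_level: np.ndarray  # cm
    insp_flows: np.ndarray  # (n_samples, n_patients), L/s
    exp_flows: np.ndarray
    supply_flow: np.ndarray  # L/s
    vent_flow: np.ndarray  # L/s
    cum_supply: np.ndarray  # L
    cum_vent: np.ndarray
    cum_insp: np.ndarray  # (n_samples, n_patients)
    insp_open: np.ndarray  # (n_samples, n_patients) bool
    events: list[tuple[float, str]]
    scenario: Scenario
    bell_model: str = "quasi_static"
    gas: GasProperties = GasProperties()
    bell_pressure: np.ndarray | None = None  # head-space gauge, second-order bell only
    cum_line_in: np.ndarray | None = None  # gas delivered into the line, second-order only

    def to_frame(self) -> pd.DataFrame:
        """One row per sample, one column per state/flow (CSV-ready)."""
        data: dict[str, np.ndarray] = {"time_s": self.time, "bell_level_cm": self.bell_level}
        for i, name in enumerate(self.node_names):
            data[f"p_{name}_cmH2O"] = self.node_pressures[:, i]
        n = self.lung_volumes.shape[1]
        for k in range(n):
            data[f"v_lung_p{k}_L"] = self.lung_volumes[:, k]
        for k in range(n):
            data[f"q_insp_p{k}_L_s"] = self.insp_flows[:, k]
        for k in range(n):
            data[f"q_exp_p{k}_L_s"] = self.exp_flows[:, k]
        data["q_supply_L_s"] = self.supply_flow
        data["q_vent_L_s"] = self.vent_flow
        data["cum_supply_L"] = self.cum_supply
        data["cum_vent_L"] = self.cum_vent
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SummaryMetrics:
    """Cycle-level metrics extracted from one run."""

    delivered_tidal: tuple[float, ...]  # L, per patient, first common breath
    time_to_target: tuple[float, ...]  # s, NaN when the target is never met
    min_inlet_pressure: tuple[float, ...]  # cmH2O, per patient
    volume_deficit_pct: tuple[float, ...]  # vs patient #1 at the common window end
    min_bell_level: float  # cm
    max_gauge_pressure: float  # cmH2O over all nodes and times
    total_supply_volume: float  # L
    total_vented_volume: float  # L
    mass_balance_residual: float  # L
    common_window_end: float  # s
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "delivered_tidal_L": list(self.delivered_tidal),
            "time_to_target_s": list(self.time_to_target),
            "min_inlet_pressure_cmH2O": list(self.min_inlet_pressure),
            "volume_deficit_pct": list(self.volume_deficit_pct),
            "min_bell_level_cm": self.min_bell_level,
            "max_gauge_pressure_cmH2O": self.max_gauge_pressure,
            "total_supply_volume_L": self.total_supply_volume,
            "total_vented_volume_L": self.total_vented_volume,
            "mass_balance_residual_L": self.mass_balance_residual,
            "common_window_end_s": self.common_window_end,
            "degenerate": self.degenerate,
        }


# ---------------------------------------------------------------------------
# constitutive helpers (unit-converted to cmH2O / L / s)
# ---------------------------------------------------------------------------


def _pipe_coeffs(pipe: PipeSpec, gas: GasProperties) -> tuple[float, float, float]:
    """(R_laminar, K_quadratic, L_inertance) in cmH2O/(L/s), /(L/s)^2, /(L/s^2)."""
    d = pipe.internal_diameter * 1e-3  # m
    area = math.pi / 4.0 * d * d
    length = max(pipe.length, 1e-6)
    if pipe.friction_model == "none":
        r_lam, k_quad = 1e-5, 1e-9
    else:
        r_si = 128.0 * MU_GAS * length / (math.pi * d**4)
        k_si = F_TURB * 8.0 * gas.density * length / (math.pi**2 * d**5)
        r_lam = r_si * 1e-3 / PA_PER_CMH2O
        k_quad = k_si * 1e-6 / PA_PER_CMH2O
    l_si = gas.density * length / area
    l_inert = l_si * 1e-3 / PA_PER_CMH2O if pipe.inertance_enabled else 0.0
    return r_lam, k_quad, l_inert


def _pipe_flow(dp: np.ndarray, r_lam: np.ndarray, k_quad: np.ndarray) -> np.ndarray:
    """Invert dp = R*Q + K*Q|Q| for Q (vectorised, odd in dp)."""
    mag = np.abs(dp)
    q = (-r_lam + np.sqrt(r_lam * r_lam + 4.0 * k_quad * mag)) / (2.0 * k_quad)
    return np.sign(dp) * q


def _series_flow(dp: np.ndarray, a: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Positive root of a*Q^2 + r*Q = dp (one-way series valve + airway R).

    Zero for nonpositive drops; ``a`` may be zero (no valve in the path).
    """
    dp = np.maximum(dp, 0.0)
    with np.errstate(invalid="ignore"):
        q = np.where(
            a > 0.0,
            (-r + np.sqrt(r * r + 4.0 * a * dp)) / (2.0 * np.where(a > 0, a, 1.0)),
            dp / r,
        )
    return q


def _valve_quad_coeff(valve: ValveSpec, gas: GasProperties) -> float:
    """a such that dp[cmH2O] = a * Q[L/s]^2 across the fully open valve."""
    c = (valve.kv / 3.6) * math.sqrt(BAR_PER_CMH2O / (gas.density / 1000.0))
    return 1.0 / (c * c)


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------


@dataclass
class _Compiled:
    node_names: tuple[str, ...]
    node_vol: np.ndarray
    esrc: np.ndarray  # -1 for the bell-jar node
    edst: np.ndarray
    e_rlam: np.ndarray
    e_kquad: np.ndarray
    e_linert: np.ndarray
    attach: np.ndarray  # patient -> node index
    R: np.ndarray
    C: np.ndarray
    peep: np.ndarray
    target: np.ndarray
    a_insp: np.ndarray
    a_exp: np.ndarray
    pip: float
    p_abs0: float
    stiff: np.ndarray  # gamma * p_abs0 / V per node
    b_max: float
    gas: GasProperties


def _compile(scenario: Scenario, gas: GasProperties) -> _Compiled:
    system = scenario.system
    pnodes = [n for n in system.nodes if n.kind in ("lead", "module")]
    node_index = {n.name: i for i, n in enumerate(pnodes)}
    node_vol = np.array([n.volume_l for n in pnodes])

    esrc, edst, er, ek, el = [], [], [], [], []
    for e in system.edges:
        if e.kind != "pipe":
            continue
        r_lam, k_quad, l_in = _pipe_coeffs(e.pipe, gas)
        esrc.append(-1 if e.src == BJS_NODE else node_index[e.src])
        edst.append(node_index[e.dst])
        er.append(r_lam)
        ek.append(k_quad)
        el.append(l_in)

    n = len(scenario.patients)
    attach = np.array([node_index[name] for name in system.patient_attachments])
    a_valve = _valve_quad_coeff(scenario.limb_valve, gas) * (
        1.0 / max(scenario.limb_valve.open_fraction, 1e-9) ** 2
    )
    pip = scenario.bjs.pip
    p_abs0 = gas.p_atm + pip
    return _Compiled(
        node_names=tuple(n_.name for n_ in pnodes),
        node_vol=node_vol,
        esrc=np.array(esrc, dtype=int),
        edst=np.array(edst, dtype=int),
        e_rlam=np.array(er),
        e_kquad=np.array(ek),
        e_linert=np.array(el),
        attach=attach,
        R=np.array([p.resistance for p in scenario.patients]),
        C=np.array([p.compliance for p in scenario.patients]),
        peep=np.array([p.peep for p in scenario.patients]),
        target=np.array([p.tidal_target for p in scenario.patients]),
        a_insp=np.full(n, a_valve),
        a_exp=np.full(n, a_valve),
        pip=pip,
        p_abs0=p_abs0,
        stiff=gas.gamma * p_abs0 / node_vol,
        b_max=scenario.bjs.dynamic_range_volume,
        gas=gas,
    )


def _phase_boundaries(controllers: Sequence[PCVConfig], duration: float) -> np.ndarray:
    """Sorted unique valve-switch times of all patients within [0, duration]."""
    times = {0.0, duration}
    for cfg in controllers:
        period, ti = cfg.period, cfg.inspiratory_time
        k0 = math.floor((0.0 - cfg.phase_offset) / period) - 1
        k1 = math.ceil((duration - cfg.phase_offset) / period) + 1
        for k in range(k0, k1 + 1):
            for t in (cfg.phase_offset + k * period, cfg.phase_offset + k * period + ti):
                if 0.0 < t < duration:
                    times.add(t)
    return np.array(sorted(times))


# ---------------------------------------------------------------------------
# main integration
# ---------------------------------------------------------------------------


def run(
    scenario: Scenario,
    solver_options: SolverOptions = SolverOptions(),
    gas: GasProperties = GasProperties(),
    bell_model: str = "quasi_static",
) -> SimulationResult:
    """Integrate one scenario and return the sampled trajectories.

    Deterministic for fixed inputs and solver options.  Raises
    :class:`ConfigurationError` if the system graph is invalid and
    :class:`SolverError` (carrying the last valid state) on integrator
    failure.
    """
    if bell_model not in ("quasi_static", "second_order"):
        raise ConfigurationError(f"unknown bell model {bell_model!r}")
    violations = validate_system(scenario.system)
    if violations:
        raise ConfigurationError("invalid system: " + "; ".join(violations))

    cmp_ = _compile(scenario, gas)
    n = len(scenario.patients)
    m = len(cmp_.node_vol)
    supply = scenario.supply
    bjs = scenario.bjs

    # state layout
    i_b = 0  # bell displaced volume (L) [quasi-static] or level (cm) [2nd order]
    i_p = 1
    i_v = i_p + m
    i_cs = i_v + n  # cumulative supply
    i_cv = i_cs + 1  # cumulative vented
    i_ci = i_cv + 1  # cumulative inspired, per patient
    n_base = i_ci + n
    if bell_model == "second_order":
        i_bv = n_base  # bell vertical velocity, cm/s
        i_pb = n_base + 1  # bell head-space gauge pressure
        i_cb = n_base + 2  # cumulative gas volume delivered into the line
        n_state = n_base + 3
    else:
        n_state = n_base

    # pipe runs with inertance enabled carry their flow as a state
    inert_idx = np.nonzero(cmp_.e_linert > 0.0)[0]
    n_ie = int(inert_idx.size)
    i_q = n_state
    n_state += n_ie

    area_cm2 = bjs.section_area
    area_l_per_cm = area_cm2 / 1000.0  # L of head space per cm of level
    servo_gain = supply.servo_gain

    # second-order bell constants (gas-spring stiffness, 0.7 damping ratio)
    if bell_model == "second_order":
        head_vol = bjs.dead_volume
        k_spring = (
            gas.gamma * cmp_.p_abs0 / head_vol * area_l_per_cm
        ) * PA_PER_CMH2O * (area_cm2 * 1e-4)  # N per cm
        k_spring_m = k_spring * 100.0  # N/m
        m_bell = bjs.bell_mass
        c_damp = 2.0 * 0.7 * math.sqrt(k_spring_m * m_bell)  # N s/m

    insp_open = np.zeros(n, dtype=bool)
    exp_open = np.zeros(n, dtype=bool)
    done = np.zeros(n, dtype=bool)
    v_start = np.zeros(n)

    def make_rhs() -> Callable[[float, np.ndarray], np.ndarray]:
        insp_mask = insp_open & ~done
        exp_mask = exp_open.copy()

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            dy = np.zeros_like(y)
            p = y[i_p : i_p + m]
            v = y[i_v : i_v + n]

            if bell_model == "quasi_static":
                b = y[i_b]
                p_bjs = cmp_.pip
                q_supply = min(max(-servo_gain * b, 0.0), supply.max_flow)
                q_vent = BELL_OVERFLOW_CONDUCTANCE * max(0.0, b - cmp_.b_max)
            else:
                b = y[i_b] * area_l_per_cm  # level(cm) -> displaced volume (L)
                p_bjs = y[i_pb]
                q_supply = min(max(-servo_gain * b, 0.0), supply.max_flow)
                q_vent = VENT_CONDUCTANCE * max(0.0, p_bjs - (cmp_.pip + bjs.escape_margin))

            p_src = np.where(cmp_.esrc < 0, p_bjs, p[np.maximum(cmp_.esrc, 0)])
            dp_e = p_src - p[cmp_.edst]
            q_e = _pipe_flow(dp_e, cmp_.e_rlam, cmp_.e_kquad)
            if n_ie:
                q_st = y[i_q : i_q + n_ie]
                q_e[inert_idx] = q_st
                dy[i_q : i_q + n_ie] = (
                    dp_e[inert_idx]
                    - cmp_.e_rlam[inert_idx] * q_st
                    - cmp_.e_kquad[inert_idx] * q_st * np.abs(q_st)
                ) / cmp_.e_linert[inert_idx]

            p_lung = v / cmp_.C
            q_insp = np.where(
                insp_mask, _series_flow(p[cmp_.attach] - p_lung, cmp_.a_insp, cmp_.R), 0.0
            )
            q_exp = np.where(
                exp_mask, _series_flow(p_lung - cmp_.peep, cmp_.a_exp, cmp_.R), 0.0
            )

            net = np.zeros(m)
            np.add.at(net, cmp_.edst, q_e)
            out_mask = cmp_.esrc >= 0
            np.subtract.at(net, cmp_.esrc[out_mask], q_e[out_mask])
            np.subtract.at(net, cmp_.attach, q_insp)
            dy[i_p : i_p + m] = cmp_.stiff * net

            q_from_bjs = q_e[cmp_.esrc < 0].sum()
            if bell_model == "quasi_static":
                dy[i_b] = q_supply - q_from_bjs - q_vent
            else:
                x_cm, v_cm = y[i_b], y[i_bv]
                force = (p_bjs - cmp_.pip) * PA_PER_CMH2O * (area_cm2 * 1e-4)  # N
                acc_m = (force - c_damp * (v_cm / 100.0)) / m_bell
                dy[i_b] = v_cm
                dy[i_bv] = acc_m * 100.0
                head_vol_t = max(bjs.dead_volume + y[i_b] * area_l_per_cm, 0.5)
                dvdt_head = q_supply - q_from_bjs - q_vent - v_cm * area_l_per_cm
                dy[i_pb] = gas.gamma * cmp_.p_abs0 / head_vol_t * dvdt_head
                dy[i_cb] = q_from_bjs

            dy[i_v : i_v + n] = q_insp - q_exp
            dy[i_cs] = q_supply
            dy[i_cv] = q_vent
            dy[i_ci : i_ci + n] = q_insp
            return dy

        return rhs

    # initial state: line at PIP, lungs at PEEP equilibrium, bell at set-point
    y = np.zeros(n_state)
    y[i_p : i_p + m] = cmp_.pip
    y[i_v : i_v + n] = cmp_.C * cmp_.peep
    if bell_model == "second_order":
        y[i_pb] = cmp_.pip

    events_log: list[tuple[float, str]] = []
    samples_t: list[np.ndarray] = []
    samples_y: list[np.ndarray] = []
    samples_insp: list[np.ndarray] = []
    samples_exp: list[np.ndarray] = []

    grid = np.arange(0.0, scenario.duration + 0.5 * solver_options.output_dt, solver_options.output_dt)
    grid = grid[grid <= scenario.duration + 1e-12]

    def record(ts: np.ndarray, ys: np.ndarray) -> None:
        if ts.size == 0:
            return
        samples_t.append(ts)
        samples_y.append(ys)
        mask_i = (insp_open & ~done)[None, :].repeat(ts.size, axis=0)
        mask_e = exp_open[None, :].repeat(ts.size, axis=0)
        samples_insp.append(mask_i)
        samples_exp.append(mask_e)

    # sample t = 0
    record(np.array([0.0]), y[None, :].copy())

    if scenario.duration > 0:
        boundaries = _phase_boundaries(scenario.controllers, scenario.duration)
        t_cur = 0.0
        for ta, tb in zip(boundaries[:-1], boundaries[1:]):
            eps = 1e-9 * max(1.0, tb)
            prev_insp = insp_open.copy()
            for k, cfg in enumerate(scenario.controllers):
                ins, exp_ = pcv_valve_command(ta + eps, cfg)
                insp_open[k], exp_open[k] = ins, exp_
            newly_insp = insp_open & ~prev_insp
            if newly_insp.any():
                for k in np.nonzero(newly_insp)[0]:
                    v_start[k] = y[i_v + k]
                    done[k] = False
                    events_log.append((float(ta), f"patient{k}: inspiration start"))
            newly_exp = prev_insp & ~insp_open
            for k in np.nonzero(newly_exp)[0]:
                events_log.append((float(ta), f"patient{k}: expiration start"))

            t_cur = ta
            while t_cur < tb - 1e-12:
                rhs = make_rhs()
                active = np.nonzero(insp_open & ~done & scenario.volume_cutoff)[0]
                evs = []
                for k in active:
                    def make_ev(kk: int):
                        def ev(t, yy):
                            return yy[i_v + kk] - (v_start[kk] + cmp_.target[kk])

                        ev.terminal = True
                        ev.direction = 1.0
                        return ev

                    evs.append(make_ev(int(k)))

                pts = grid[(grid > t_cur + 1e-12) & (grid < tb - 1e-12)]
                t_eval = np.unique(np.concatenate([pts, [tb]]))
                sol = solve_ivp(
                    rhs,
                    (t_cur, tb),
                    y,
                    method=solver_options.method,
                    rtol=solver_options.rtol,
                    atol=solver_options.atol,
                    max_step=solver_options.max_step,
                    t_eval=t_eval,
                    events=evs or None,
                    dense_output=False,
                )
                if sol.status == -1:
                    raise SolverError(sol.message, t_cur, y)
                if sol.status == 1:  # a volume target was hit
                    t_hit = min(te[0] for te in sol.t_events if te.size)
                    st = np.asarray(sol.t, dtype=float)
                    sy = np.asarray(sol.y, dtype=float)
                    if st.size:
                        keep = st <= t_hit + 1e-15
                        record(st[keep], sy[:, keep].T)
                    # mark every patient whose target event fired at t_hit
                    y = None
                    for i, te in enumerate(sol.t_events):
                        if te.size and te[0] <= t_hit + 1e-12:
                            k = int(active[i])
                            done[k] = True
                            events_log.append(
                                (float(te[0]), f"patient{k}: tidal target reached")
                            )
                            if y is None:
                                y = sol.y_events[i][0].copy()
                    t_cur = float(t_hit)
                else:
                    record(sol.t, sol.y.T)
                    y = sol.y[:, -1].copy()
                    t_cur = tb

    t_all = np.concatenate(samples_t)
    y_all = np.vstack(samples_y)
    mi_all = np.vstack(samples_insp)
    me_all = np.vstack(samples_exp)
    # drop duplicate time stamps (segment ends coincide with grid points)
    keep = np.concatenate([[True], np.diff(t_all) > 1e-12])
    t_all, y_all, mi_all, me_all = t_all[keep], y_all[keep], mi_all[keep], me_all[keep]

    return _assemble_result(
        scenario, cmp_, solver_options, bell_model, t_all, y_all, mi_all, me_all, events_log,
        i_b, i_p, i_v, i_cs, i_cv, i_ci, m, n, area_l_per_cm, supply, servo_gain, gas,
    )


def _assemble_result(
    scenario, cmp_, opts, bell_model, t, y, mask_i, mask_e, events,
    i_b, i_p, i_v, i_cs, i_cv, i_ci, m, n, area_l_per_cm, supply, servo_gain, gas,
) -> SimulationResult:
    p = y[:, i_p : i_p + m]
    v = y[:, i_v : i_v + n]
    p_bell = cum_line = None
    if bell_model == "quasi_static":
        bell_level = 1000.0 * y[:, i_b] / scenario.bjs.section_area
        b_vol = y[:, i_b]
    else:
        bell_level = y[:, i_b]
        b_vol = y[:, i_b] * area_l_per_cm
        p_bell = y[:, i_ci + n + 1]
        cum_line = y[:, i_ci + n + 2]
    q_supply = np.clip(-servo_gain * b_vol, 0.0, supply.max_flow)
    if bell_model == "quasi_static":
        q_vent = BELL_OVERFLOW_CONDUCTANCE * np.maximum(0.0, b_vol - cmp_.b_max)
    else:
        q_vent = VENT_CONDUCTANCE * np.maximum(
            0.0, p_bell - (cmp_.pip + scenario.bjs.escape_margin)
        )

    p_lung = v / cmp_.C[None, :]
    q_insp = np.where(
        mask_i,
        _series_flow(p[:, cmp_.attach] - p_lung, cmp_.a_insp[None, :], cmp_.R[None, :]),
        0.0,
    )
    q_exp = np.where(
        mask_e,
        _series_flow(p_lung - cmp_.peep[None, :], cmp_.a_exp[None, :], cmp_.R[None, :]),
        0.0,
    )

    # flag relief-vent onsets in the event log
    venting = q_vent > 1e-9
    onsets = np.nonzero(venting[1:] & ~venting[:-1])[0]
    ev = list(events)
    for i in onsets:
        ev.append((float(t[i + 1]), "relief vent open"))
    ev.sort(key=lambda pair: pair[0])

    return SimulationResult(
        time=t,
        node_names=cmp_.node_names,
        node_pressures=p,
        lung_volumes=v,
        bell_level=bell_level,
        insp_flows=q_insp,
        exp_flows=q_exp,
        supply_flow=q_supply,
        vent_flow=q_vent,
        cum_supply=y[:, i_cs],
        cum_vent=y[:, i_cv],
        cum_insp=y[:, i_ci : i_ci + n],
        insp_open=mask_i,
        events=ev,
        scenario=scenario,
        bell_model=bell_model,
        gas=gas,
        bell_pressure=p_bell,
        cum_line_in=cum_line,
    )


# ---------------------------------------------------------------------------
# fixtures and summaries
# ---------------------------------------------------------------------------


def worst_case_scenario(
    n_patients: int = 10,
    duration: float = 3.0,
    tidal: float = 0.5,
    bjs: BellJarSpec = BellJarSpec(),
    supply: SupplySpec = SupplySpec(),
) -> Scenario:
    """The synchronous-inspiration stress fixture.

    Ten patients on a 25 m linear line (3 m lead + 10 x 2.2 m modules), all
    starting inspiration at t = 0 with 0.5 L targets, PIP 24 cmH2O
    (28 kg / 1166.7 cm2), Kv 1.8 m3/h per limb and the supply capped at
    4 L/s.  R and C are spread evenly across their design ranges
    (R = 6-18 cmH2O/(L/s), C = 0.03-0.06 L/cmH2O) in attachment order, so
    the farthest patient is also the slowest-filling one.  PEEP is zero:
    unrestricted lungs make the synchronous demand as large as possible.
    """
    rs = np.linspace(6.0, 18.0, n_patients)
    cs = np.linspace(0.03, 0.06, n_patients)
    patients = tuple(
        PatientSpec(resistance=float(r), compliance=float(c), tidal_target=tidal,
                    respiratory_rate=20.0, peep=0.0)
        for r, c in zip(rs, cs)
    )
    layout = LayoutSpec(shape="linear", patients_per_limb=(n_patients,),
                        max_patients=max(10, n_patients))
    system = build_system(layout, patients, bjs, supply)
    controllers = tuple(PCVConfig(respiratory_rate=20.0, ie_ratio=(1.0, 2.0)) for _ in patients)
    from .network import patients_with_distances

    return Scenario(
        system=system,
        patients=patients_with_distances(system, patients),
        bjs=bjs,
        supply=supply,
        controllers=controllers,
        duration=duration,
        synchronous_start=True,
        limb_valve=ValveSpec(kv=1.8),
    )


def summarize(result: SimulationResult) -> SummaryMetrics:
    """Reduce a run to its cycle-level metrics.

    Delivered tidal volumes and the volume-deficit figures refer to the
    first breath: the deficit of patient k is 100 * (V1 - Vk) / V1 evaluated
    at the common inspiratory-window end (the earliest first-window close
    over patients), with volumes measured above each patient's start-of-
    inspiration baseline.
    """
    scn = result.scenario
    n = result.lung_volumes.shape[1]
    t = result.time
    if t.size < 2:
        nan = tuple([float("nan")] * n)
        return SummaryMetrics(
            delivered_tidal=nan, time_to_target=nan, min_inlet_pressure=nan,
            volume_deficit_pct=nan, min_bell_level=float("nan"),
            max_gauge_pressure=float("nan"), total_supply_volume=float("nan"),
            total_vented_volume=float("nan"), mass_balance_residual=float("nan"),
            common_window_end=float("nan"), degenerate=True,
        )

    # first inspiratory window per patient
    starts, ends = [], []
    for cfg in scn.controllers:
        period, ti = cfg.period, cfg.inspiratory_time
        local = (0.0 - cfg.phase_offset) % period
        start = 0.0 if local < ti else cfg.phase_offset % period
        if start < 0:
            start += period
        starts.append(start)
        ends.append(start + ti - (local if local < ti else 0.0))
    common_end = min(min(ends), t[-1])

    attach_names = scn.system.patient_attachments
    name_to_col = {nm: i for i, nm in enumerate(result.node_names)}

    delivered, ttt, min_inlet, base = [], [], [], []
    for k in range(n):
        s_idx = np.searchsorted(t, starts[k])
        e_idx = np.searchsorted(t, min(ends[k], t[-1]))
        e_idx = min(e_idx, t.size - 1)
        v0 = result.lung_volumes[s_idx, k]
        base.append(v0)
        v_win = result.lung_volumes[s_idx : e_idx + 1, k] - v0
        delivered.append(float(v_win[-1]) if v_win.size else float("nan"))
        target = scn.patients[k].tidal_target
        reached = np.nonzero(result.lung_volumes[:, k] - v0 >= target - 1e-9)[0]
        ttt.append(float(t[reached[0]]) if reached.size else float("nan"))
        col = name_to_col[attach_names[k]]
        p_win = result.node_pressures[s_idx : e_idx + 1, col]
        min_inlet.append(float(p_win.min()) if p_win.size else float("nan"))

    ce_idx = min(int(np.searchsorted(t, common_end)), t.size - 1)
    v_at_ce = result.lung_volumes[ce_idx, :] - np.array(base)
    v1 = v_at_ce[0]
    deficit = [100.0 * (v1 - v_at_ce[k]) / v1 if v1 > 0 else float("nan") for k in range(n)]

    # gas mass balance over the whole run
    cmp_ = _compile(scn, result.gas)
    d_node = float(
        np.sum(
            cmp_.node_vol
            * (result.node_pressures[-1] - result.node_pressures[0])
            / (cmp_.gas.gamma * cmp_.p_abs0)
        )
    )
    if result.cum_line_in is None:
        # quasi-static bell: full supply-to-lungs balance
        d_bell = (
            float(result.bell_level[-1] - result.bell_level[0]) * scn.bjs.section_area / 1000.0
        )
        residual = (
            float(result.cum_supply[-1])
            - d_bell
            - float(result.cum_vent[-1])
            - d_node
            - float(result.cum_insp[-1].sum())
        )
    else:
        # second-order bell: balance the distribution line (the head-space
        # side is conserved by construction of its pressure ODE)
        residual = (
            float(result.cum_line_in[-1]) - d_node - float(result.cum_insp[-1].sum())
        )

    return SummaryMetrics(
        delivered_tidal=tuple(delivered),
        time_to_target=tuple(ttt),
        min_inlet_pressure=tuple(min_inlet),
        volume_deficit_pct=tuple(deficit),
        min_bell_level=float(result.bell_level.min()),
        max_gauge_pressure=float(result.node_pressures.max()),
        total_supply_volume=float(result.cum_supply[-1]),
        total_vented_volume=float(result.cum_vent[-1]),
        mass_balance_residual=residual,
        common_window_end=float(common_end),
    )


# ---------------------------------------------------------------------------
# single-lung and closed-loop helpers
# ---------------------------------------------------------------------------


def single_lung_response(
    patient: PatientSpec,
    inlet_pressure: float,
    duration: float,
    valve: ValveSpec | None = None,
    gas: GasProperties = GasProperties(),
    v0: float = 0.0,
    n_samples: int = 400,
) -> tuple[np.ndarray, np.ndarray]:
    """Fill one lung from an ideal constant-pressure inlet.

    With ``valve=None`` this is the bare linear R-C lung, whose closed form
    is V(t) = C p (1 - exp(-t / RC)) (from V(0) = 0); with a valve, the Kv
    element is in series with the airway resistance.
    Returns (t, V).
    """
    a = _valve_quad_coeff(valve, gas) / max(valve.open_fraction, 1e-9) ** 2 if valve else 0.0

    def rhs(t, y):
        dp = inlet_pressure - y[0] / patient.compliance
        q = _series_flow(np.array([dp]), np.array([a]), np.array([patient.resistance]))[0]
        qr = 0.0
        if dp < 0:  # allow passive emptying through R when above equilibrium
            qr = dp / patient.resistance
        return [q + qr]

    t_eval = np.linspace(0.0, duration, n_samples)
    sol = solve_ivp(rhs, (0.0, duration), [v0], t_eval=t_eval, method="LSODA",
                    rtol=1e-9, atol=1e-12)
    return sol.t, sol.y[0]


def _lung_empty(patient: PatientSpec, a: float, duration: float, v0: float) -> float:
    """Passive expiration through the limb to the PEEP threshold; returns V(end)."""

    def rhs(t, y):
        dp = y[0] / patient.compliance - patient.peep
        q = _series_flow(np.array([dp]), np.array([a]), np.array([patient.resistance]))[0]
        return [-q]

    sol = solve_ivp(rhs, (0.0, duration), [v0], method="LSODA", rtol=1e-8, atol=1e-11)
    return float(sol.y[0, -1])


def vg_closed_loop(
    patient: PatientSpec,
    vg: VGConfig,
    pcv: PCVConfig,
    valve: ValveSpec = ValveSpec(),
    gas: GasProperties = GasProperties(),
    duration: float = 120.0,
    inlet_pressure: float | None = None,
) -> pd.DataFrame:
    """Breath-by-breath volume-guarantee loop against a single simulated lung.

    The lung fills from a constant-PIP inlet for the current inspiratory
    fraction of each cycle, empties through the expiratory limb to PEEP for
    the rest, and the measured tidal volume drives :func:`vg_adapt` once per
    breath.  Returns one row per breath: time, inspiratory fraction,
    measured tidal and alarm flag.
    """
    pip = inlet_pressure if inlet_pressure is not None else BellJarSpec().pip
    a = _valve_quad_coeff(valve, gas) / max(valve.open_fraction, 1e-9) ** 2
    period = pcv.period
    frac = pcv.inspiratory_fraction
    v = patient.compliance * patient.peep
    rows = []
    t = 0.0
    while t < duration - 1e-9:
        ti = frac * period
        _, vv = single_lung_response(patient, pip, ti, valve=valve, gas=gas, v0=v, n_samples=50)
        v_end = float(vv[-1])
        measured = v_end - v
        v = _lung_empty(patient, a, period - ti, v_end)
        frac, alarm = vg_adapt(frac, measured, vg, dt=period)
        t += period
        rows.append({"time_s": t, "inspiratory_fraction": frac,
                     "measured_tidal_L": measured, "alarm": alarm})
    return pd.DataFrame(rows)
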