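"""Per-patient ventilation logic.

With PIP fixed system-wide by the bell weight, the only per-patient control
handles are *timing*: the respiratory rate, the inspiration/expiration duty
cycle, and (in assisted mode) patient-triggered phase switching.  The two
switch valves of each patient operate strictly in counterphase — a single
three-way valve is forbidden because inspiration and expiration may share
no element.

Modes
-----
* Pressure-controlled (PCV): fixed RR and I:E ratio; the inspiratory valve
  is open for the inspiratory fraction of each cycle.
* Volume-guaranteed (VG): a slow integral adaptation of the duty cycle
  (time to set-point ~1 min) that nudges the delivered tidal volume toward
  its target, alarming until the target is reached.  The admitted duty range
  is I:E 1:1 to 1:3 (inspiratory fraction 1/4 to 1/2).
* Assisted: inspiration triggered by a pressure dip at the inflow sensor;
  expiration triggered when inflow decays to a set percentage of its peak or
  a maximum inspiration time elapses.

Note on ratio conventions: the duty range is stated here as clinical
I:E = 1:1 .. 1:3 (inspiration never longer than expiration), nominal 1:2,
i.e. inspiration one third of the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .components import SpecError

__all__ = [
    "PCVConfig",
    "VGConfig",
    "AssistConfig",
    "AlarmState",
    "ALARM_KINDS",
    "pcv_valve_command",
    "vg_adapt",
    "assist_detect_inspiration",
    "assist_detect_expiration",
    "evaluate_alarms",
    "CycleMetrics",
]

#: admitted inspiratory fraction range, I:E between 1:1 and 1:3
INSP_FRACTION_MIN = 0.25
INSP_FRACTION_MAX = 0.5

ALARM_KINDS = frozenset(
    {"tidal_out_of_range", "phase_timeout", "minute_volume_unmet", "volume_guarantee_unmet"}
)


def _insp_fraction(ie_ratio: tuple[float, float]) -> float:
    i, e = ie_ratio
    if i <= 0 or e <= 0:
        raise SpecError(f"ie_ratio parts must be positive, got {ie_ratio}")
    return i / (i + e)


@dataclass(frozen=True)
class PCVConfig:
    """Pressure-controlled ventilation timing for one patient.

    ``ie_ratio`` is the clinical inspiration:expiration pair, nominal (1, 2);
    the inspiratory fraction must lie in [1/4, 1/2] (I:E 1:3 .. 1:1).
    ``phase_offset`` shifts this patient's cycle, enabling asynchrony.
    """

    respiratory_rate: float = 20.0
    ie_ratio: tuple[float, float] = (1.0, 2.0)
    phase_offset: float = 0.0
    rr_bounds: tuple[float, float] = (4.0, 60.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ie_ratio", (float(self.ie_ratio[0]), float(self.ie_ratio[1])))
        lo, hi = self.rr_bounds
        if not lo <= self.respiratory_rate <= hi:
            raise SpecError(f"respiratory_rate {self.respiratory_rate} outside bounds [{lo}, {hi}]")
        f = _insp_fraction(self.ie_ratio)
        if not INSP_FRACTION_MIN - 1e-12 <= f <= INSP_FRACTION_MAX + 1e-12:
            raise SpecError(
                f"ie_ratio {self.ie_ratio} gives inspiratory fraction {f:.3f} outside "
                f"[{INSP_FRACTION_MIN}, {INSP_FRACTION_MAX}]"
            )

    @property
    def period(self) -> float:
        """Breath period in s."""
        return 60.0 / self.respiratory_rate

    @property
    def inspiratory_fraction(self) -> float:
        return _insp_fraction(self.ie_ratio)

    @property
    def inspiratory_time(self) -> float:
        return self.period * self.inspiratory_fraction


@dataclass(frozen=True)
class VGConfig:
    """Volume-guaranteed adaptation settings.

    A clamped integral controller moves the inspiratory fraction toward the
    value delivering ``tidal_target``; the gain is sized as 3/settling_time
    per cycle-normalised error, so a feasible target is approached in about
    one settling time (default 60 s).
    """

    tidal_target: float = 0.5
    settling_time: float = 60.0
    duty_bounds: tuple[float, float] = (INSP_FRACTION_MIN, INSP_FRACTION_MAX)
    tidal_tolerance: float = 0.10  # fraction of target within which the alarm clears

    def __post_init__(self) -> None:
        if not self.tidal_target > 0:
            raise SpecError("tidal_target must be positive")
        if not self.settling_time > 0:
            raise SpecError("settling_time must be positive")
        lo, hi = self.duty_bounds
        if not (0 < lo < hi <= 1):
            raise SpecError(f"invalid duty_bounds {self.duty_bounds}")

    @property
    def adaptation_gain(self) -> float:
        """Fractional duty change per second per unit normalised tidal error."""
        return 3.0 / self.settling_time


@dataclass(frozen=True)
class AssistConfig:
    """Patient-trigger thresholds for assisted ventilation.

    Defaults are conventional ICU values: a 2 cmH2O dip below baseline starts
    inspiration; inspiration ends when inflow decays to 25% of its peak or
    after 1.5 s, whichever comes first.
    """

    trigger_pressure_drop: float = 2.0
    flow_termination_fraction: float = 0.25
    max_inspiration_time: float = 1.5

    def __post_init__(self) -> None:
        if not self.trigger_pressure_drop > 0:
            raise SpecError("trigger_pressure_drop must be positive")
        if not 0 < self.flow_termination_fraction < 1:
            raise SpecError("flow_termination_fraction must lie in (0, 1)")
        if not self.max_inspiration_time > 0:
            raise SpecError("max_inspiration_time must be positive")


@dataclass
class AlarmState:
    """Latched set of active alarms; an alarm clears when its condition does."""

    active_alarms: set[str] = field(default_factory=set)

    def update(self, raised: Iterable[str], cleared: Iterable[str] = ()) -> "AlarmState":
        raised = set(raised)
        unknown = raised - ALARM_KINDS
        if unknown:
            raise SpecError(f"unknown alarm kinds {sorted(unknown)}")
        self.active_alarms |= raised
        self.active_alarms -= set(cleared)
        return self

    def __bool__(self) -> bool:
        return bool(self.active_alarms)


def pcv_valve_command(t: float, config: PCVConfig) -> tuple[bool, bool]:
    """Counterphase valve command at time ``t``: (inspiratory_open, expiratory_open).

    Exactly one of the two is open at any time; the cycle has period 60/RR
    and the inspiratory window occupies the inspiratory fraction of it.
    """
    if t < 0:
        raise SpecError(f"t must be nonnegative, got {t}")
    local = (t - config.phase_offset) % config.period
    insp = local < config.inspiratory_time
    return insp, not insp


def vg_adapt(
    current_inspiratory_fraction: float,
    measured_tidal: float,
    config: VGConfig,
    dt: float,
) -> tuple[float, bool]:
    """One volume-guarantee update step over an interval ``dt`` (s).

    Returns the updated inspiratory fraction (clamped to the duty bounds)
    and the alarm flag, active while the measured tidal volume deviates from
    target by more than the configured tolerance.  A shortfall lengthens
    inspiration; an overshoot shortens it.
    """
    lo, hi = config.duty_bounds
    if not lo <= current_inspiratory_fraction <= hi:
        raise SpecError(
            f"inspiratory fraction {current_inspiratory_fraction} outside duty bounds [{lo}, {hi}]"
        )
    err_norm = (config.tidal_target - measured_tidal) / config.tidal_target
    new = current_inspiratory_fraction + config.adaptation_gain * dt * err_norm
    new = min(hi, max(lo, new))
    alarm = abs(measured_tidal - config.tidal_target) > config.tidal_tolerance * config.tidal_target
    return new, alarm


def assist_detect_inspiration(
    inlet_pressure_history: Sequence[float],
    baseline: float,
    config: AssistConfig,
) -> bool:
    """True when the patient's inspiratory effort should trigger a breath.

    Fires (inclusively) when the inflow-sensor pressure has dipped to
    ``baseline - trigger_pressure_drop`` or below at any point of the
    supplied expiratory-phase history.
    """
    threshold = baseline - config.trigger_pressure_drop
    return any(p <= threshold for p in inlet_pressure_history)


def assist_detect_expiration(
    current_flow: float,
    peak_flow: float,
    elapsed: float,
    config: AssistConfig,
) -> bool:
    """True when an assisted inspiration should cycle off.

    Fires when inflow has decayed (inclusively) to the configured fraction
    of its running peak, or when the maximum inspiration time has elapsed.
    """
    if elapsed >= config.max_inspiration_time:
        return True
    if peak_flow <= 0:
        return False
    return current_flow <= config.flow_termination_fraction * peak_flow


@dataclass(frozen=True)
class CycleMetrics:
    """Measurements from one completed breath cycle of one patient."""

    delivered_tidal: float
    minute_volume: float
    inspiration_timed_out: bool = False
    expiration_timed_out: bool = False


def evaluate_alarms(
    metrics: CycleMetrics,
    tidal_range: tuple[float, float],
    minute_volume_target: float,
    vg: VGConfig | None = None,
    state: AlarmState | None = None,
) -> AlarmState:
    """Map one cycle's measurements onto the alarm set.

    Raised alarms: tidal volume outside the set range; any phase timed out;
    minute volume below target; volume-guarantee target not reached (when a
    VG configuration is active).  Alarms latch in ``state`` and clear when
    their condition does.
    """
    state = state if state is not None else AlarmState()
    lo, hi = tidal_range
    raised, cleared = [], []

    def flag(name: str, condition: bool) -> None:
        (raised if condition else cleared).append(name)

    flag("tidal_out_of_range", not lo <= metrics.delivered_tidal <= hi)
    flag("phase_timeout", metrics.inspiration_timed_out or metrics.expiration_timed_out)
    flag("minute_volume_unmet", metrics.minute_volume < minute_volume_target)
    if vg is not None:
        unmet = abs(metrics.delivered_tidal - vg.tidal_target) > vg.tidal_tolerance * vg.tidal_target
        flag("volume_guarantee_unmet", unmet)
    return state.update(raised, cleared)
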