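"""Static design arithmetic for the multi-patient ventilator.

Dead-volume ledger, pipe geometry, and the worst-case instantaneous-
withdrawal PIP-drop bound that underwrites patient uncoupling: if all ten
patients simultaneously withdrew their full 0.5 L tidal volume from the
system Windkessel *instantaneously* — a bound stricter than any dynamic
scenario, since neither the supply nor the bell can respond — the shared
drive pressure must still stay within a few percent of PIP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .components import (
    BellJarSpec,
    GasProperties,
    PipeSpec,
    SpecError,
    bell_level_excursion,
    pip_from_bell,
)

__all__ = [
    "DeadVolumeLedger",
    "WorstCaseResult",
    "ConstraintFlag",
    "DesignReport",
    "pipe_volume_per_m",
    "total_dead_volume",
    "worst_case_pip_drop",
    "design_report",
    "nominal_ledger",
    "NOMINAL_MAIN_LINE_VOLUME_L",
]

#: As-specified dead volume of the nominal 25 m main line (L).  The design
#: figure corresponds to ~24.95 m of equivalent 2" length; recomputing from
#: exactly 25.0 m of 50.8 mm pipe gives 50.68 L.  The ledger carries the
#: as-specified component value.
NOMINAL_MAIN_LINE_VOLUME_L = 50.65


@dataclass(frozen=True)
class DeadVolumeLedger:
    """Itemised gas dead volume of the pressure-buffering Windkessel (L)."""

    bjs_dead: float
    bell_buffer: float
    main_line: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("bjs_dead", "bell_buffer", "main_line"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be nonnegative")
        object.__setattr__(self, "total", self.bjs_dead + self.bell_buffer + self.main_line)

    def to_dict(self) -> dict:
        return {
            "bjs_dead_L": self.bjs_dead,
            "bell_buffer_L": self.bell_buffer,
            "main_line_L": self.main_line,
            "total_L": self.total,
        }


@dataclass(frozen=True)
class WorstCaseResult:
    """Outcome of the instantaneous-withdrawal pressure-drop bound."""

    p_initial: float
    p_final: float
    deviation: float  # percent, signed
    mode: str

    def to_dict(self) -> dict:
        return {
            "p_initial_cmH2O": self.p_initial,
            "p_final_cmH2O": self.p_final,
            "deviation_pct": self.deviation,
            "mode": self.mode,
        }


@dataclass(frozen=True)
class ConstraintFlag:
    """A named pass/fail design check with its computed margin."""

    name: str
    passed: bool
    margin: float
    units: str

    def to_dict(self) -> dict:
        return {"name": self.name, "passed": self.passed, "margin": self.margin, "units": self.units}


@dataclass(frozen=True)
class DesignReport:
    """Aggregate static design ledger for one system configuration."""

    pip: float
    ledger: DeadVolumeLedger
    worst_case: WorstCaseResult
    level_excursion_limit: float  # cm
    constraint_flags: tuple[ConstraintFlag, ...]

    def to_dict(self) -> dict:
        return {
            "pip_cmH2O": self.pip,
            "dead_volume": self.ledger.to_dict(),
            "worst_case": self.worst_case.to_dict(),
            "level_excursion_limit_cm": self.level_excursion_limit,
            "constraints": [f.to_dict() for f in self.constraint_flags],
        }


def pipe_volume_per_m(internal_diameter: float) -> float:
    """Dead volume per metre of pipe (L/m) from its internal diameter (mm).

    pi/4 * d^2 per metre of run; for the 2" (50.8 mm) line this is 2.027,
    i.e. the familiar 2.03 L/m.
    """
    if not internal_diameter > 0:
        raise SpecError(f"internal_diameter must be positive, got {internal_diameter}")
    return math.pi / 4.0 * (internal_diameter * 1e-3) ** 2 * 1000.0


def total_dead_volume(bjs_dead: float, bell_buffer: float, main_line: float) -> DeadVolumeLedger:
    """Assemble the dead-volume ledger; ``total`` is the exact sum."""
    return DeadVolumeLedger(bjs_dead=bjs_dead, bell_buffer=bell_buffer, main_line=main_line)


def nominal_ledger() -> DeadVolumeLedger:
    """The nominal 10-patient ledger: 15.27 + 10 + 50.65 = 75.92 L."""
    return total_dead_volume(
        bjs_dead=BellJarSpec().dead_volume,
        bell_buffer=BellJarSpec().dynamic_range_volume,
        main_line=NOMINAL_MAIN_LINE_VOLUME_L,
    )


def worst_case_pip_drop(
    p0: float,
    v0: float,
    withdrawn: float,
    mode: str = "gauge_proportional",
    gas: GasProperties = GasProperties(),
) -> WorstCaseResult:
    """Bound the PIP drop after an instantaneous withdrawal from the Windkessel.

    Parameters
    ----------
    p0
        Initial gauge pressure, cmH2O.
    v0
        Initial gas dead volume, L.
    withdrawn
        Volume withdrawn instantaneously, L (e.g. 10 patients x 0.5 L).
    mode
        ``"gauge_proportional"`` (default): the gauge pressure scales with the
        volume ratio, p_final = p0 * v0 / (v0 + withdrawn), equivalently
        deviation% = -100 * withdrawn / (v0 + withdrawn).  This is the
        design-sizing relation: for 5 L out of 75.92 L at 24 cmH2O it gives
        22.52 cmH2O, a -6.18% deviation.
        ``"adiabatic_absolute"``: a literal adiabatic expansion of the
        absolute pressure, p_abs_final = (p0 + p_atm) * (v0/(v0+withdrawn))**gamma,
        returned as gauge — provided for sensitivity analysis.  Because the
        operating gauge pressure is tiny against the atmosphere, this mode
        yields a far larger (sub-atmospheric) drop; the two modes agree only
        at zero withdrawal.
    """
    if not v0 > 0:
        raise SpecError(f"v0 must be positive, got {v0}")
    if withdrawn < 0:
        raise SpecError(f"withdrawn must be nonnegative, got {withdrawn}")
    v1 = v0 + withdrawn
    if mode == "gauge_proportional":
        p_final = p0 * v0 / v1
    elif mode == "adiabatic_absolute":
        p_final = (p0 + gas.p_atm) * (v0 / v1) ** gas.gamma - gas.p_atm
    else:
        raise SpecError(f"unknown worst-case mode {mode!r}")
    deviation = 100.0 * (p_final - p0) / p0 if p0 != 0 else 0.0
    return WorstCaseResult(p_initial=p0, p_final=p_final, deviation=deviation, mode=mode)


def design_report(
    bjs: BellJarSpec,
    pipes: Sequence[PipeSpec],
    n_patients: int,
    tidal_worst: float,
    mode: str = "gauge_proportional",
    gas: GasProperties = GasProperties(),
    main_line_volume: float | None = None,
) -> DesignReport:
    """Aggregate PIP, dead-volume ledger, worst-case bound and constraint checks.

    ``main_line_volume`` overrides the main-line dead volume computed from
    ``pipes`` (used when carrying an as-specified ledger component rather
    than recomputing from geometry).
    """
    if n_patients < 1:
        raise SpecError(f"n_patients must be >= 1, got {n_patients}")
    if not tidal_worst > 0:
        raise SpecError(f"tidal_worst must be positive, got {tidal_worst}")
    pip = pip_from_bell(bjs.bell_mass, bjs.section_area)
    if main_line_volume is None:
        main_line_volume = sum(p.volume_l for p in pipes)
    ledger = total_dead_volume(bjs.dead_volume, bjs.dynamic_range_volume, main_line_volume)
    withdrawn = n_patients * tidal_worst
    worst = worst_case_pip_drop(pip, ledger.total, withdrawn, mode=mode, gas=gas)
    excursion_limit = bell_level_excursion(bjs.dynamic_range_volume, bjs.section_area)

    flags = (
        ConstraintFlag(
            name="worst_case_withdrawal_within_bell_buffer",
            passed=withdrawn <= bjs.dynamic_range_volume,
            margin=bjs.dynamic_range_volume - withdrawn,
            units="L",
        ),
        ConstraintFlag(
            name="worst_case_excursion_within_level_range",
            passed=bell_level_excursion(withdrawn, bjs.section_area) <= excursion_limit,
            margin=excursion_limit - bell_level_excursion(withdrawn, bjs.section_area),
            units="cm",
        ),
        ConstraintFlag(
            name="worst_case_deviation_within_10pct",
            passed=abs(worst.deviation) <= 10.0,
            margin=10.0 - abs(worst.deviation),
            units="%",
        ),
    )
    return DesignReport(
        pip=pip,
        ledger=ledger,
        worst_case=worst,
        level_excursion_limit=excursion_limit,
        constraint_flags=flags,
    )
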