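"""Physical elements of the multiple-emergency-ventilator (MEV) circuit.

The MEV delivers the same oxygen mixture at the same peak inspiratory
pressure (PIP) to up to ten intubated patients.  The pressure source is a
water-sealed bell jar: the bell's weight over its cross-section fixes the
delivered gauge pressure by Archimedes' law, and its level excursion buffers
instantaneous volume demand.  Each patient hangs off a common 2" distribution
line through an independent inspiratory limb (switch valve + one-way valve)
and exhales through an independent expiratory limb with an adjustable PEEP
threshold.

Unit conventions, package-wide
------------------------------
pressure   cmH2O gauge (1 cmH2O = 0.980665 mbar)
volume     L
flow       L/s (valve coefficients Kv in m3/h, the industry convention)
length     m for pipes, cm for bell level
mass       kg
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SpecError",
    "GasProperties",
    "BellJarSpec",
    "PipeSpec",
    "ValveSpec",
    "PatientSpec",
    "SupplySpec",
    "CMH2O_PER_BAR",
    "BAR_PER_CMH2O",
    "pip_from_bell",
    "bell_mass_for_pip",
    "bell_level_excursion",
    "valve_flow",
    "lung_derivative",
    "relief_vent_flow",
]

#: 1 bar expressed in cmH2O (conventional water column).
CMH2O_PER_BAR = 1.0 / 0.000980665
#: 1 cmH2O expressed in bar.
BAR_PER_CMH2O = 0.000980665

#: Default atmospheric pressure, cmH2O absolute (~1.013 bar).
P_ATM_CMH2O = 1033.0


class SpecError(ValueError):
    """An element specification violates its physical invariants."""


@dataclass(frozen=True)
class GasProperties:
    """Thermodynamic properties of the delivered gas mixture.

    Parameters
    ----------
    gamma
        Adiabatic exponent; 1.4 for a diatomic gas at room temperature.
    density
        Gas density in kg/m3.  Default 1.30 kg/m3, an O2-rich mixture at
        room conditions.
    p_atm
        Atmospheric pressure in cmH2O absolute.
    """

    gamma: float = 1.4
    density: float = 1.30
    p_atm: float = P_ATM_CMH2O

    def __post_init__(self) -> None:
        if not self.gamma > 1.0:
            raise SpecError(f"gamma must exceed 1, got {self.gamma}")
        if not self.density > 0:
            raise SpecError(f"density must be positive, got {self.density}")
        if not self.p_atm > 0:
            raise SpecError(f"p_atm must be positive, got {self.p_atm}")


@dataclass(frozen=True)
class BellJarSpec:
    """Geometry and mass of the gravity pressure source.

    The bell's weight resting on its cross-section fixes the delivered gauge
    pressure (``pip``); the head space above the set-point water level is the
    dead volume, and the level may excurse by ``dynamic_range_volume`` before
    the bell bottoms out.  Above ``pip + escape_margin`` the water seal vents
    gas outside — the intrinsic barotrauma protection.

    Defaults are the nominal 10-patient sizing: 28 kg on 1166.7 cm2 giving
    PIP = 24 cmH2O, 15.27 L of head-space dead volume, ±10 L (±8.6 cm) of
    dynamic range and a 1 cmH2O margin to the safety gas escape.
    """

    bell_mass: float = 28.0
    section_area: float = 1166.7
    dead_volume: float = 15.27
    dynamic_range_volume: float = 10.0
    escape_margin: float = 1.0

    def __post_init__(self) -> None:
        if not self.bell_mass >= 0:
            raise SpecError(f"bell_mass must be nonnegative, got {self.bell_mass}")
        for name in ("section_area", "dead_volume", "dynamic_range_volume", "escape_margin"):
            if not getattr(self, name) > 0:
                raise SpecError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def pip(self) -> float:
        """Delivered gauge pressure in cmH2O (derived, never stored)."""
        return pip_from_bell(self.bell_mass, self.section_area)

    @property
    def level_range_cm(self) -> float:
        """Level excursion in cm corresponding to the dynamic volume range."""
        return bell_level_excursion(self.dynamic_range_volume, self.section_area)


@dataclass(frozen=True)
class PipeSpec:
    """A straight run of distribution pipe.

    The 2" (50.8 mm ID) stainless line is deliberately oversized: its dead
    volume (2.03 L/m) is part of the pressure-buffering Windkessel and its
    friction drop is negligible at the flows of interest.
    """

    length: float
    internal_diameter: float = 50.8  # mm
    friction_model: str = "darcy_weisbach"  # or "none"
    inertance_enabled: bool = False

    def __post_init__(self) -> None:
        if not self.internal_diameter > 0:
            raise SpecError(f"internal_diameter must be positive, got {self.internal_diameter}")
        if self.length < 0:
            raise SpecError(f"length must be nonnegative, got {self.length}")
        if self.friction_model not in ("none", "darcy_weisbach"):
            raise SpecError(f"unknown friction_model {self.friction_model!r}")

    @property
    def volume_l(self) -> float:
        """Gas dead volume of the run, in L."""
        area_m2 = math.pi / 4.0 * (self.internal_diameter * 1e-3) ** 2
        return area_m2 * self.length * 1000.0


@dataclass(frozen=True)
class ValveSpec:
    """A flow element characterised by its Kv coefficient.

    ``kv`` is the water flow in m3/h through the fully open valve at 1 bar
    drop.  The lumped series of each patient's switch valve and pressure/flow
    sensors is represented by a single Kv = 1.8 m3/h.  ``open_fraction`` is
    clamped to [0, 1]; one-way valves block reverse flow entirely.
    """

    kv: float = 1.8
    open_fraction: float = 1.0
    one_way: bool = False

    def __post_init__(self) -> None:
        if not self.kv > 0:
            raise SpecError(f"kv must be positive, got {self.kv}")
        clamped = min(1.0, max(0.0, self.open_fraction))
        object.__setattr__(self, "open_fraction", clamped)


@dataclass(frozen=True)
class PatientSpec:
    """Single-compartment respiratory mechanics plus ventilation targets.

    ``resistance`` (R, cmH2O/(L/s)) and ``compliance`` (C, L/cmH2O) define a
    linear one-compartment lung; volume is measured above functional residual
    capacity.  PEEP is the expiratory threshold, not a lung property.
    Physiologic design ranges: R = 6–18, C = 0.03–0.06, tidal 0.3–0.5 L,
    RR 14–30 acts/min.
    """

    resistance: float
    compliance: float
    tidal_target: float = 0.5
    respiratory_rate: float = 20.0
    peep: float = 0.0
    distance_from_bjs: float = 0.0

    #: sanity bounds for R (cmH2O/(L/s)); generously wider than the design range
    _R_BOUNDS = (0.5, 100.0)

    def __post_init__(self) -> None:
        lo, hi = self._R_BOUNDS
        if not lo <= self.resistance <= hi:
            raise SpecError(
                f"resistance {self.resistance} outside physiologic range [{lo}, {hi}]"
            )
        if not self.compliance > 0:
            raise SpecError(f"compliance must be positive, got {self.compliance}")
        if not self.tidal_target > 0:
            raise SpecError(f"tidal_target must be positive, got {self.tidal_target}")
        if not self.respiratory_rate > 0:
            raise SpecError(f"respiratory_rate must be positive, got {self.respiratory_rate}")
        if self.peep < 0:
            raise SpecError(f"peep must be nonnegative, got {self.peep}")


@dataclass(frozen=True)
class SupplySpec:
    """The medical gas supply feeding the bell jar.

    A pressure-regulated source (2–3 bar relative wall gas) servoes the bell
    level back to its set-point, saturating at ``max_flow`` (4 L/s nominal,
    enough to cover an accidental patient detachment).
    """

    max_flow: float = 4.0
    source_pressure: float = 2.5  # bar relative
    #: regulator servo gain, L/s of supply per L of bell-level deficit
    servo_gain: float = 2.0

    def __post_init__(self) -> None:
        if not self.max_flow > 0:
            raise SpecError(f"max_flow must be positive, got {self.max_flow}")
        if not self.servo_gain > 0:
            raise SpecError(f"servo_gain must be positive, got {self.servo_gain}")


# ---------------------------------------------------------------------------
# constitutive laws
# ---------------------------------------------------------------------------


def pip_from_bell(bell_mass: float, section_area: float) -> float:
    """Gauge pressure (cmH2O) delivered by a bell of given mass and section.

    Archimedes/weight-over-area: p[cmH2O] = 1000 * M[kg] / A[cm2], since
    1 cmH2O equals 1 gram-force per cm2.

    >>> pip_from_bell(28, 1166.7)  # doctest: +ELLIPSIS
    23.99...
    """
    if not section_area > 0:
        raise SpecError(f"section_area must be positive, got {section_area}")
    if bell_mass < 0:
        raise SpecError(f"bell_mass must be nonnegative, got {bell_mass}")
    return 1000.0 * bell_mass / section_area


def bell_mass_for_pip(pip: float, section_area: float) -> float:
    """Bell mass (kg) required for a target gauge pressure; inverse of
    :func:`pip_from_bell`."""
    if not section_area > 0:
        raise SpecError(f"section_area must be positive, got {section_area}")
    if pip < 0:
        raise SpecError(f"pip must be nonnegative, got {pip}")
    return pip * section_area / 1000.0


def bell_level_excursion(volume_displaced: float, section_area: float) -> float:
    """Signed bell level change (cm) for a displaced gas volume (L).

    level[cm] = 1000 * V[L] / A[cm2]; antisymmetric in V.
    """
    if not section_area > 0:
        raise SpecError(f"section_area must be positive, got {section_area}")
    return 1000.0 * volume_displaced / section_area


def valve_flow(
    delta_p: float,
    valve: ValveSpec,
    gas: GasProperties = GasProperties(),
) -> float:
    """Volumetric flow (L/s) through a Kv-rated valve at a given drop (cmH2O).

    Incompressible Kv law with specific-gravity correction,

        Q[m3/h] = open_fraction * Kv * sqrt(dp[bar] / (rho/1000)),

    adequate because operating drops (tens of cmH2O) are far below the
    choked-flow regime.  Two-way valves pass flow of either sign (odd in
    ``delta_p``); one-way valves return 0 for reverse drops.  The flow is
    continuous (and zero) at ``delta_p = 0``.
    """
    frac = valve.open_fraction
    if frac == 0.0 or delta_p == 0.0:
        return 0.0
    if delta_p < 0.0 and valve.one_way:
        return 0.0
    sign = 1.0 if delta_p > 0 else -1.0
    dp_bar = abs(delta_p) * BAR_PER_CMH2O
    q_m3h = frac * valve.kv * math.sqrt(dp_bar / (gas.density / 1000.0))
    return sign * q_m3h / 3.6  # m3/h -> L/s


def lung_derivative(volume_above_frc: float, airway_pressure: float, patient: PatientSpec) -> float:
    """Rate of lung volume change dV/dt (L/s) of the single-compartment lung.

    dV/dt = (p_aw - V/C) / R: the airway pressure in excess of the elastic
    recoil V/C drives flow through the linear airway resistance.
    """
    return (airway_pressure - volume_above_frc / patient.compliance) / patient.resistance


def relief_vent_flow(
    gauge_pressure: float,
    bjs: BellJarSpec,
    conductance: float = 5.0,
) -> float:
    """Gas flow (L/s) escaping through the water seal at excess pressure.

    Zero at or below ``pip + escape_margin``; above that the seal bubbles gas
    outside at ``conductance`` L/s per cmH2O of excess.  This caps the
    maximum steady pressure anywhere in the network.
    """
    threshold = bjs.pip + bjs.escape_margin
    return conductance * max(0.0, gauge_pressure - threshold)
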