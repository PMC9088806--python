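# Methods

## Scope and units

`mevsim` models a ten-patient shared-pressure ventilator as a lumped
pneumatic network plus static design calculators. Units are fixed
package-wide: pressure in cmH2O gauge (1 cmH2O = 0.980665 mbar), volumes in
L, flows in L/s, pipe lengths in m, bell level in cm, mass in kg. Valve
coefficients keep the industry Kv convention (m³/h at 1 bar, water).

## Physical elements

**Bell jar.** The delivered pressure is purely gravimetric:
`PIP = 1000·M/A` with `M` in kg and `A` in cm², because 1 cmH2O equals
1 gf/cm². The head space above the set-point water level (15.27 L by
default) plus the ±10 L level excursion form the bell's share of the
pressure-buffering Windkessel. Above `PIP + escape_margin` (margin 1 cmH2O)
the water seal vents; `relief_vent_flow` models this as a linear
conductance (5 L/s per cmH2O of excess) above an inclusive threshold, which
caps every steady-state pressure in the network.

Two bell dynamics are offered. The default is *quasi-static*: the bell
weight is always balanced by gas pressure, the bell-jar node holds PIP
exactly, and the level is a pure volume integrator. No manufacturer
inertia/friction data exist, so the alternative *second-order* model (a
damped mass riding the gas spring of the head space, damping ratio 0.7
against the computed spring stiffness) is provided for sensitivity studies
only; with it the head-space pressure becomes a state and the relief vent
acts on it directly, which is how the intrinsic-safety cap can be seen
engaging during regulator overshoot.

**Valves.** The lumped series of each patient's switch valve and
pressure/flow sensors is a single Kv = 1.8 m³/h element obeying the
incompressible Kv law with specific-gravity correction,
`Q[m³/h] = open_fraction·Kv·√(Δp[bar]/(ρ/1000))`. Operating drops (tens of
cmH2O, ~2 % of an atmosphere) are far below choked-flow regimes, so a
compressible valve law would change nothing measurable. The default gas
density is 1.30 kg/m³ (an O₂-rich mixture at room conditions),
configurable. Both limbs of a patient carry the same lumped Kv; the
expiratory limb's coefficient is configurable independently of nothing else
in the default build (one `ValveSpec` per scenario) simply because no
separate figure exists for it.

**Lungs.** Linear single compartment, `dV/dt = (p_aw − V/C)/R`, volume
measured above functional residual capacity. PEEP is a property of the
expiratory limb (a threshold element discharging to atmosphere), not of the
lung; expiration stops when recoil pressure meets PEEP.

**Pipes.** The 2" line (ID 50.8 mm, 2.027 L/m ≈ the familiar 2.03 L/m) is
discretised one node per 2.2 m patient module plus a 3 m lead node per
limb, matching the physical modularity (200 cm pipe + 20 cm tee).
Friction is `Δp = R_lam·Q + K·Q|Q|`: the laminar term is Hagen–Poiseuille,
the quadratic term uses a constant Darcy friction factor f = 0.03 (a blend
adequate for the short, grossly oversized runs, where the total drop at
full demand is well under 1 cmH2O). Per-segment inertance (`ρ·l/A`) can be
enabled, adding the segment flow as a state; it reproduces the
tens-of-milliseconds inlet-pressure dips qualitatively but is off by
default because the exact friction/inertance correlations of the reference
design are not published — transient dip depths from this model are
therefore indicative, not validated.

**Gas storage.** Each node uses polytropic compressibility linearised at
the operating point: `dP/dt = γ·p_abs0/V · (ΣQ_in − ΣQ_out)` with γ = 1.4
and `p_abs0 = p_atm + PIP` (p_atm default 1033 cmH2O). The linearisation
error is second-order in the few-percent pressure swings seen in operation
and makes the mass-balance bookkeeping exact.

**Supply.** A pressure-regulated source servoes the bell level to its
set-point: `Q = clip(gain·deficit, 0, 4 L/s)`, gain 2 s⁻¹ by default. The
4 L/s cap is the design's supply dimensioning.

## Worst-case withdrawal bound

`worst_case_pip_drop` implements two modes. The default,
`gauge_proportional`, scales the gauge pressure with the volume ratio:
`p1 = p0·V0/(V0+ΔV)`, equivalently `deviation = −ΔV/(V0+ΔV)`; for 5 L out
of 75.92 L at 24 cmH2O this gives 22.52 cmH2O and −6.18 %, the design's
sizing relation. The `adiabatic_absolute` mode applies the literal
adiabatic expansion to absolute pressure,
`p_abs1 = (p0+p_atm)·(V0/V1)^γ`; because the operating gauge pressure is
~2 % of an atmosphere this yields a drastically larger (sub-atmospheric,
−66.3 cmH2O) figure. The two relations answer different questions — the
first bounds the *gauge* drive available to the lungs when the bell keeps
feeding the line, the second describes a sealed rigid volume with no
source. Both are exposed, the gauge-proportional one is the default, and
the divergence is covered by tests rather than silently resolved.

The nominal dead-volume ledger carries the as-specified component values
(15.27 + 10 + 50.65 = 75.92 L). Recomputing the main line from exactly
25.0 m of 50.8 mm pipe gives 50.67 L; the 50.65 L figure corresponds to
slightly under 25 m of equivalent length and is kept verbatim as the
design constant, with the geometric recomputation available through
`pipe_volume_per_m`.

## Controllers

The only per-patient handles under a fixed PIP are timing. The I:E ratio
convention is clinical inspiration:expiration, nominal 1:2 (inspiration one
third of the cycle) within the admitted 1:1–1:3 range, i.e. an inspiratory
fraction in [1/4, 1/2]; a reading in which expiration is the shorter phase
would contradict that range and is not used. PCV opens the two switch
valves in strict counterphase (never both, never neither).

Volume guarantee is a clamped integral law: per update,
`f ← clip(f + (3/T_s)·dt·(target−measured)/target, 1/4, 1/2)` with settling
time `T_s = 60 s`, so a feasible target is approached in about one settling
time and the duty range is never left regardless of inputs. The alarm
stays active while the measured tidal volume deviates more than ±10 % from
target (both thresholds configurable). Feasibility depends on RR, PEEP and
the patient's mechanics: with a fixed 24 cmH2O drive, low-RR/zero-PEEP
settings can over-deliver even at the 1:3 duty floor, which the alarm then
reports — the closed-loop tests use RR 30 with PEEP 8, where a 0.4 L target
lies inside the reachable band.

Assist triggers use conventional ICU defaults, all configurable: a 2 cmH2O
dip below baseline starts inspiration (inclusive threshold); inflow
decaying to 25 % of its running peak, or a 1.5 s timeout, ends it.

In the simulated worst case the engine applies a volume-guarantee cut-off:
each inspiratory valve closes when its breath's delivered volume reaches
the patient's tidal target. Under this controller all ten patients receive
their full 0.5 L inside the common window, so the farthest-patient volume
deficit measured at the window end is zero — the network imposes no
residual deficit; the uncoupling burden shows up instead as the transient
inlet-pressure dip and a slightly later time-to-target for distal patients.

## Worst-case fixture

`worst_case_scenario()` builds the stress case: ten patients on one linear
limb (3 m lead + 10 × 2.2 m = 25 m, farthest patient at 25 m), synchronous
inspiration from rest, 0.5 L targets, PEEP 0 (unrestricted lungs maximise
the synchronous demand), PIP 24 cmH2O, Kv 1.8 m³/h per limb, supply capped
at 4 L/s, and R/C spread evenly over R ∈ [6, 18], C ∈ [0.03, 0.06] in
attachment order (the ranges are design inputs; the even spread in
attachment order is this package's reproducible choice, and it makes the
farthest patient also the mechanically slowest). One 3 s breath cycle
(RR 20, I:E 1:2) is simulated.

## Numerics

The network ODE is stiff (node stiffness `γ·p_abs/V` ≈ 330 cmH2O/L against
near-zero pipe friction), so the integrator is BDF with rtol 1e-6,
atol 1e-8. Valve phase switches are exact segment boundaries (no event
hunting for known times); volume-target cut-offs are terminal integrator
events, with simultaneous hits (identical patients) handled in one pass.
Output is sampled on a 1 ms grid, fine enough to resolve the
tens-of-milliseconds inlet transients. Gas mass balance
(supply − inspired − vented − Δstored) is reported per run and sits at
integrator precision (~1e-14 L for the default model). Degenerate inputs:
a zero-duration run returns a summary flagged `degenerate` with NaN
metrics rather than failing; invalid graphs are refused before
integration with the full violation list.

## Synthetic populations

`generate_population` samples patients uniformly and independently within
the design ranges (R 6–18, C 0.03–0.06, tidal 0.3–0.5 L, RR 14–30/min)
from a single seeded generator. This emulates the *spread* of clinical
conditions the device must serve, not their joint distribution in any real
cohort: real R and C are correlated with pathology and with each other,
and real patients are nonlinear and time-varying. Passing tests therefore
demonstrate robustness across the declared parameter box, not clinical
performance.

## Known limitations

- Single-compartment linear lungs; no airway nonlinearity, no spontaneous
  effort in the PCV/VG simulations (assist triggers are evaluated as logic,
  not closed-loop patient effort).
- Pipe friction uses a constant turbulent friction factor and the reference
  design's friction/inertance details are unavailable, so transient dip
  magnitudes are qualitative.
- Humidity, temperature, FiO₂ transport and CO₂ are out of scope; the gas
  is a single species with fixed properties.
- The second-order bell model's inertia/damping are assumptions, not data.
- Cross-contamination, sensors, alarms hardware and mechanical structure
  are represented only insofar as they constrain the pneumatic topology
  (independent expiratory limbs, one-way valves, no shared
  inspiratory/expiratory element).
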