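"""Underwater hypogravity design: ballast masses, force balance, drag limit.

A submerged body segment of mass m (kg) and volume V (m^3) experiences its
weight m*g downward and the Archimedes force rho_w*(V + V_b)*g upward, where
V_b is the volume of an attached ballast of mass m_b and density rho_b.
Lunar gravity is simulated by choosing m_b so that the net downward force
equals the segment's weight under the target gravity:

    (m + m_b) g  -  rho_w (V + m_b / rho_b) g  =  m g_t            (ZF = 0)

which gives the closed form

    m_b = (m (g_t - g) + rho_w V g) / (g (1 - rho_w / rho_b)).

By default the ballast is pure compensation hardware (the right-hand side is
the segment's lunar weight, not the segment-plus-ballast weight); the
alternative accounting, in which the ballast is part of the simulated mass,
is available via ``include_ballast_in_target``.

A drag criterion limits hand speed for dynamic tasks: requiring the drag
force (1/2) rho_w C_d A v^2 to stay below a fraction f of a reference weight
W gives v_max = sqrt(2 f W / (rho_w C_d A)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

G_EARTH = 9.81       # m/s^2
G_LUNAR = 1.626      # m/s^2
RHO_WATER = 1000.0   # kg/m^3 (freshwater tank)
RHO_LEAD = 11340.0   # kg/m^3

#: ballast mass above which the added moment of inertia becomes noticeable
INERTIA_THRESHOLD_KG = 3.0

#: maximum slow hand-movement speed keeping drag below 10% of the forearm
#: reference weight (m/s)
MAX_SLOW_HAND_SPEED = 0.47


@dataclass(frozen=True)
class SimulationConstants:
    g_earth: float = G_EARTH
    g_target: float = G_LUNAR
    rho_water: float = RHO_WATER
    rho_ballast: float = RHO_LEAD
    include_ballast_in_target: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.g_target < self.g_earth:
            raise ValueError("require 0 < g_target < g_earth")
        if not self.rho_water > 0:
            raise ValueError("rho_water must be > 0")


class BallastError(ValueError):
    """Raised when no non-negative ballast mass satisfies the balance.

    ``required_flotation_kg`` is the mass of (ideal, massless-volume)
    flotation that would be needed instead: the segment already sinks harder
    than its target-gravity weight.
    """

    def __init__(self, msg: str, required_flotation_kg: float):
        super().__init__(msg)
        self.required_flotation_kg = required_flotation_kg


@dataclass
class BallastEntry:
    segment: str
    segment_mass: float      # kg
    segment_volume: float    # m^3
    ballast_mass: float      # kg
    ballast_volume: float    # m^3
    ballast_density: float   # kg/m^3
    residual_force: float    # N, from substituting back into ZF = 0


@dataclass
class BallastPlan:
    entries: list[BallastEntry] = field(default_factory=list)
    constants: SimulationConstants = field(default_factory=SimulationConstants)

    @property
    def total_ballast_mass(self) -> float:
        return sum(e.ballast_mass for e in self.entries)


def _balance_residual(
    m: float, V: float, m_b: float, c: SimulationConstants, rho_b: float
) -> float:
    """Net downward force minus the target weight (N); zero when balanced."""
    target = (m + m_b) * c.g_target if c.include_ballast_in_target else m * c.g_target
    return (m + m_b) * c.g_earth - c.rho_water * (V + m_b / rho_b) * c.g_earth - target


def ballast_mass(
    segment_mass: float,
    segment_volume: float,
    constants: SimulationConstants = SimulationConstants(),
    ballast_density: Optional[float] = None,
    allow_buoyant: bool = False,
) -> tuple[float, float]:
    """Solve the force balance for the ballast mass of one segment.

    Returns ``(m_b, residual)`` with the residual obtained by substituting
    m_b back into the balance (should be ~0 to rounding).

    ``allow_buoyant`` permits a compensation density below water (e.g. an
    inflatable pillow offsetting head weight): the same balance is solved,
    the hardware then provides net lift instead of net weight.

    Raises
    ------
    ValueError
        if the ballast would float (rho_b <= rho_water) and buoyant
        hardware was not explicitly allowed.
    BallastError
        if the solution is negative (the segment needs the opposite kind
        of hardware); the exception carries the required mass.
    """
    if not (segment_mass > 0 and segment_volume > 0):
        raise ValueError("segment_mass and segment_volume must be > 0")
    c = constants
    rho_b = c.rho_ballast if ballast_density is None else ballast_density
    if rho_b <= c.rho_water and not allow_buoyant:
        raise ValueError(
            f"ballast density {rho_b} kg/m^3 <= water density {c.rho_water}; "
            "ballast would float (pass allow_buoyant=True for flotation "
            "hardware such as a neck pillow)"
        )
    num = segment_mass * (c.g_target - c.g_earth) + c.rho_water * segment_volume * c.g_earth
    den = c.g_earth * (1.0 - c.rho_water / rho_b)
    if c.include_ballast_in_target:
        den -= c.g_target
    m_b = num / den
    if m_b < 0:
        raise BallastError(
            f"segment (m={segment_mass} kg, V={segment_volume} m^3) already "
            f"sinks harder than its target-gravity weight; requires "
            f"{-m_b:.6g} kg of flotation instead of ballast",
            required_flotation_kg=-m_b,
        )
    residual = _balance_residual(segment_mass, segment_volume, m_b, c, rho_b)
    return m_b, residual


def plan_ballast(
    segments: Mapping[str, tuple[float, float]] | Iterable[tuple[str, float, float]],
    constants: SimulationConstants = SimulationConstants(),
    ballast_density_overrides: Optional[Mapping[str, float]] = None,
) -> BallastPlan:
    """Ballast plan for a set of segments.

    ``segments`` maps segment name -> (mass kg, volume m^3), or is an
    iterable of (name, mass, volume) triples.  ``ballast_density_overrides``
    allows e.g. an inflatable head-compensation entry with rho_b < rho_water
    (buoyant hardware is permitted only for entries with such an override;
    the same balance equation applies).
    """
    if isinstance(segments, Mapping):
        items = [(name, mv[0], mv[1]) for name, mv in segments.items()]
    else:
        items = [tuple(x) for x in segments]  # type: ignore[list-item]
    overrides = dict(ballast_density_overrides or {})
    plan = BallastPlan(constants=constants)
    for name, m, V in items:
        rho_b = overrides.get(name, constants.rho_ballast)
        m_b, res = ballast_mass(m, V, constants, ballast_density=rho_b,
                                allow_buoyant=name in overrides)
        plan.entries.append(
            BallastEntry(
                segment=name,
                segment_mass=m,
                segment_volume=V,
                ballast_mass=m_b,
                ballast_volume=m_b / rho_b,
                ballast_density=rho_b,
                residual_force=res,
            )
        )
    return plan


def validate_balance(
    plan: BallastPlan, constants: Optional[SimulationConstants] = None
) -> float:
    """Recompute ZF for every entry, independently of the solver.

    Returns the maximum |residual| (N) over entries; 0 for an empty plan.
    """
    c = constants if constants is not None else plan.constants
    worst = 0.0
    for e in plan.entries:
        res = _balance_residual(
            e.segment_mass, e.segment_volume, e.ballast_mass, c, e.ballast_density
        )
        worst = max(worst, abs(res))
    return worst


def max_hand_speed(
    reference_weight: float,
    drag_fraction: float = 0.1,
    drag_area: float = 0.02,
    drag_coefficient: float = 1.0,
    rho_water: float = RHO_WATER,
) -> float:
    """Drag-limited hand speed (m/s): v = sqrt(2 f W / (rho C_d A)).

    ``reference_weight`` is the weight (N) whose fraction ``drag_fraction``
    the drag force may not exceed; by convention the forearm's simulated
    (target-gravity) weight.
    """
    vals = (reference_weight, drag_fraction, drag_area, drag_coefficient, rho_water)
    if any(not v > 0 for v in vals):
        raise ValueError("all max_hand_speed inputs must be > 0")
    if not drag_fraction < 1:
        raise ValueError("drag_fraction must be in (0, 1)")
    return math.sqrt(
        2.0 * drag_fraction * reference_weight
        / (rho_water * drag_coefficient * drag_area)
    )


def inertia_flag(
    plan: BallastPlan,
    lever_arms: Mapping[str, float],
    threshold_mass: float = INERTIA_THRESHOLD_KG,
) -> dict[str, dict[str, float | bool]]:
    """Point-mass moment of inertia of each ballast about its rotation axis.

    ``lever_arms`` maps segment name -> lever arm r (m); I = m_b r^2.
    A segment is flagged when its ballast mass exceeds ``threshold_mass``
    (3 kg by default), the level at which the added inertia becomes
    noticeable for slow upper-limb motion.
    """
    out: dict[str, dict[str, float | bool]] = {}
    for e in plan.entries:
        r = float(lever_arms.get(e.segment, 0.0))
        if r < 0:
            raise ValueError(f"lever arm for {e.segment!r} must be >= 0")
        out[e.segment] = {
            "I": e.ballast_mass * r * r,
            "flagged": bool(e.ballast_mass > threshold_mass),
        }
    return out
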