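"""Design the underwater ballast that simulates lunar gravity.

For each body segment (mass, volume) we solve the vertical force balance
(weight - Archimedes force - lunar weight = 0) for the lead ballast mass
attached at the segment's CoM, then verify the balance and check the
drag-limited hand speed for slow dynamic tasks.
"""

from lunarcom.hypogravity import (
    SimulationConstants,
    inertia_flag,
    max_hand_speed,
    plan_ballast,
    validate_balance,
)

# mean male segments: (mass kg, volume m^3)
segments = {
    "forearm": (1.55, 1.37e-3),
    "upper_arm": (2.70, 2.70e-3),
    "torso": (38.8, 44.71e-3),
}

constants = SimulationConstants()          # 9.81 -> 1.626 m/s^2, lead in fresh water
plan = plan_ballast(segments, constants)

print(f"{'segment':<10} {'mass kg':>8} {'vol dm3':>8} {'ballast kg':>11} {'residual N':>11}")
for e in plan.entries:
    print(f"{e.segment:<10} {e.segment_mass:8.2f} {e.segment_volume*1e3:8.2f} "
          f"{e.ballast_mass:11.3f} {e.residual_force:11.2e}")
print(f"worst |sum F| after solving: {validate_balance(plan):.2e} N")

flags = inertia_flag(plan, {"forearm": 0.12, "upper_arm": 0.15, "torso": 0.25})
for name, f in flags.items():
    note = "NOTICEABLE" if f["flagged"] else "negligible"
    print(f"added inertia {name}: {f['I']:.4f} kg m^2 ({note})")

# drag criterion: keep drag below 10% of the forearm's simulated lunar weight
w_forearm = segments["forearm"][0] * constants.g_target
v = max_hand_speed(w_forearm, drag_fraction=0.10, drag_area=0.012,
                   drag_coefficient=1.0)
print(f"max slow-hand speed for <10% drag: {v*100:.0f} cm/s")
# The ballast masses are what a dive technician would strap on each segment;
# residuals ~1e-13 N confirm the closed-form solution balances exactly.
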