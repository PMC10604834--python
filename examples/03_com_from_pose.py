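"""Segmental whole-body CoM of a seated pose, relative to the pelvis.

Poses the seated template upright and slouched-forward, computes the
segmental CoM (Plagenhoef mass fractions and proximal coefficients) and
reports the pelvis-relative displacements the study's regression consumes.
"""

import numpy as np

from lunarcom.anthropometry import default_segment_table
from lunarcom.com import body_com
from lunarcom.mocap import Pose3D
from lunarcom.synthetic import _ARM_STATIC, GeneratorConfig, generate_cohort, seated_keypoints

cfg = GeneratorConfig()
person = generate_cohort(cfg, np.random.default_rng(4))[0]
model = default_segment_table(person.sex, total_mass=person.mass_kg)
print(f"participant: {person.sex}, {person.height_m:.2f} m, {person.mass_kg:.1f} kg")
print(f"modeled upper-body mass: {model.modeled_mass:.1f} kg "
      f"({100 * model.modeled_mass / model.total_mass:.0f}% of body mass)")

for label, pitch_deg, slouch in (("upright", 0.0, 1.0),
                                 ("forward lean", 25.0, 1.0),
                                 ("slouched lean", 25.0, 0.85)):
    kp = seated_keypoints(person, np.radians(pitch_deg), slouch, _ARM_STATIC)
    pose = Pose3D(0, 0.0, kp, np.ones(25, bool), np.zeros(25))
    s = body_com(pose, model)
    print(f"{label:>14}: CoM ({s.com[0]:5.1f}, {s.com[1]:5.1f}, {s.com[2]:5.1f}) cm"
          f"   dY = {s.d_y:6.2f} cm, dZ = {s.d_z:6.2f} cm")
# dY = pelvis_y - com_y (downward shift positive), dZ = pelvis_z - com_z
# (posterior shift positive): leaning forward drops the CoM toward the hip
# (dY rises toward zero) and moves it anterior (dZ more negative).
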