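"""Evaluate 2D keypoint quality with PCK against annotations.

Simulates detections as annotations corrupted by Gaussian pixel error and
reports PCK at several thresholds; mirrors how markerless capture quality
is screened before trusting triangulated CoM estimates.
"""

import numpy as np

from lunarcom.mocap import Pose2D, pck
from lunarcom.synthetic import (
    _ARM_STATIC,
    GeneratorConfig,
    default_camera_rig,
    generate_cohort,
    seated_keypoints,
)

cfg = GeneratorConfig()
person = generate_cohort(cfg, np.random.default_rng(0))[0]
cam = default_camera_rig(cfg)["cam1"]
kp3 = seated_keypoints(person, 0.1, 1.0, _ARM_STATIC)
px = cam.project(kp3)

annotated = Pose2D(0, np.column_stack([px, np.ones(25)]))
rng = np.random.default_rng(8)
for sigma in (2.0, 8.0, 20.0):
    noisy = Pose2D(0, np.column_stack([px + rng.normal(0, sigma, px.shape),
                                       np.ones(25)]))
    scores = {a: pck(noisy, annotated, alpha=a) for a in (0.05, 0.1, 0.2)}
    print(f"pixel error sd {sigma:5.1f} px -> PCK@0.05 {scores[0.05]:5.1f}  "
          f"PCK@0.1 {scores[0.1]:5.1f}  PCK@0.2 {scores[0.2]:5.1f}")
# PCK counts keypoints within alpha x (torso diagonal) of the annotation;
# clean detections score 100, heavy corruption drags the score down.
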