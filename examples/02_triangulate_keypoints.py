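"""Triangulate multi-camera keypoint JSON into 3D skeletons.

Builds a three-camera rig, renders one synthetic seated trial into the
OpenPose JSON dialect, reads the files back and recovers the 3D poses by
confidence-weighted DLT, reporting the reconstruction error.
"""

import tempfile
from pathlib import Path

import numpy as np

from lunarcom.mocap import read_openpose_frames, triangulate_poses
from lunarcom.synthetic import (
    GeneratorConfig,
    default_camera_rig,
    generate_cohort,
    generate_trial,
    render_views,
)

cfg = GeneratorConfig(fps=10.0, window_s=3.0)
person = generate_cohort(cfg, np.random.default_rng(1))[0]
trial = generate_trial(person, "1/6g", "dynamic", 1.0, cfg,
                       np.random.default_rng(2), on_unreachable="clip")
rig = default_camera_rig(cfg)

with tempfile.TemporaryDirectory() as tmp:
    render_views(trial, rig, tmp, np.random.default_rng(3),
                 pixel_noise_sd=1.0, dropout_p=0.02)
    names = sorted(rig)
    seqs = [read_openpose_frames(Path(tmp) / n) for n in names]
    poses = triangulate_poses([rig[n] for n in names], seqs, fps=cfg.fps)

truth = {i: kp for i, _, kp in trial.frames}
errs = [np.linalg.norm(p.xyz[p.valid] - truth[p.frame_index][p.valid], axis=1)
        for p in poses]
errs = np.concatenate(errs)
rms = np.concatenate([p.reproj_rms[p.valid] for p in poses])
print(f"frames: {len(poses)}, keypoints triangulated: {errs.size}")
print(f"median 3D error: {np.median(errs):.3f} cm (1 px noise, 3 cameras at 2 m)")
print(f"median reprojection RMS: {np.median(rms):.2f} px")
# At 1 px image noise the 3D keypoints come back to a few millimetres,
# comfortably below the centimetre-scale CoM effects under study.
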