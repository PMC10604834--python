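"""End-to-end study processing: JSON tree -> tidy window-mean table.

Glue over the other modules: read a study directory (per-trial, per-camera
keypoint JSON plus calibration and metadata), triangulate each trial,
compute the segmental CoM per frame, summarise the ET windows and return
one tidy row per (trial, window) ready for the regression stage.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .anthropometry import default_segment_table
from .com import body_com, summarize_trial
from .mocap import load_calibration, read_openpose_frames, triangulate_poses


def process_trial(
    trial_dir,
    cameras: dict,
    sex: str,
    mass_kg: float,
    et_min: float,
    fps: float = 30.0,
    window_s: float = 5.0,
    max_window_s: float = 60.0,
    min_views: int = 2,
    meta: Optional[dict] = None,
):
    """Triangulate one trial directory and summarise its ET windows."""
    trial_dir = Path(trial_dir)
    cam_names = sorted(cameras)
    seqs = []
    for name in cam_names:
        cam_dir = trial_dir / name
        seqs.append(read_openpose_frames(cam_dir) if cam_dir.is_dir() else [])
    poses = triangulate_poses([cameras[n] for n in cam_names], seqs,
                              min_views=min_views, fps=fps)
    model = default_segment_table(sex, total_mass=mass_kg)
    samples = [body_com(p, model) for p in poses]
    meta = meta or {}
    return summarize_trial(
        samples,
        participant=meta.get("participant", trial_dir.name),
        sex=sex,
        gravity=meta.get("gravity", ""),
        task=meta.get("task", ""),
        load_kg=float(meta.get("load_kg", 0.0)),
        et_min=et_min,
        window_s=window_s,
        max_window_s=max_window_s,
    )


def run_study(study_dir, min_views: int = 2) -> pd.DataFrame:
    """Process a full study tree into the tidy analysis table.

    Expects ``calib.yaml``, ``study.yaml`` and ``meta.csv`` at the root and
    one subdirectory per trial (as written by
    :func:`lunarcom.synthetic.generate_study`).  Returns one row per
    (trial, window) with columns ``participant, sex, gravity, g_level,
    task_name, task, load_kg, window, dY_cm, dZ_cm, n_frames``.
    """
    study_dir = Path(study_dir)
    cameras = load_calibration(study_dir / "calib.yaml")
    with open(study_dir / "study.yaml", "r", encoding="utf-8") as fh:
        study_cfg = yaml.safe_load(fh)
    fps = float(study_cfg.get("fps", 30.0))
    window_s = float(study_cfg.get("window_s", 5.0))
    max_window_s = float(study_cfg.get("max_window_s", 60.0))
    meta = pd.read_csv(study_dir / "meta.csv")

    rows = []
    for rec in meta.to_dict("records"):
        summary = process_trial(
            study_dir / rec["trial_id"], cameras,
            sex=rec["sex"], mass_kg=float(rec["mass_kg"]),
            et_min=float(rec["et_min"]), fps=fps,
            window_s=window_s, max_window_s=max_window_s,
            min_views=min_views, meta=rec,
        )
        for label, w in summary.windows.items():
            rows.append({
                "trial_id": rec["trial_id"],
                "participant": rec["participant"],
                "sex": rec["sex"],
                "gravity": rec["gravity"],
                "g_level": 1 if rec["gravity"] == "1g" else 0,
                "task_name": rec["task"],
                "task": 1 if rec["task"] == "dynamic" else 0,
                "load_kg": rec["load_kg"],
                "window": label,
                "dY_cm": w.mean_d_y,
                "dZ_cm": w.mean_d_z,
                "n_frames": w.n_frames,
            })
    return pd.DataFrame(rows)


def relative_to_start(df: pd.DataFrame) -> pd.DataFrame:
    """Re-express window displacements as changes from each trial's start.

    Alternative dependent variable: subtracts the start-window value of
    ``dY_cm`` and ``dZ_cm`` within each trial, so the regression measures
    within-trial drift instead of the absolute pelvis-relative posture.
    """
    out = df.copy()
    for col in ("dY_cm", "dZ_cm"):
        start = (out[out["window"] == "start"]
                 .set_index("trial_id")[col])
        out[col] = out[col] - out["trial_id"].map(start).to_numpy()
    return out


def analysis_rows(df: pd.DataFrame, n_per_sex: dict[str, int]) -> pd.DataFrame:
    """Trim the tidy table to the configured per-sex analysis row counts."""
    parts = []
    for sex, n in n_per_sex.items():
        sub = df[df["sex"] == sex]
        parts.append(sub.iloc[:n])
    return pd.concat(parts, ignore_index=True)
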