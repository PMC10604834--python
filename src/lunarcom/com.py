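"""Whole-body CoM per frame, pelvis-relative displacement, ET windows.

The whole-body centre of mass is the segmental weighted sum

    CoM = (1/M) * sum_(i,j) m_ij [ P_i + k_ij (P_j - P_i) ],

with m_ij = mass_fraction * total mass and M the summed modeled mass.  The
hip joint keypoint (pelvis, MidHip) is the reference point; displacements
are reported along the proximodistal (Y) and anterior-posterior (Z) axes:

    dY = pelvis_y - com_y     (downward CoM shift positive, by default)
    dZ = pelvis_z - com_z     (posterior CoM shift positive, by default)

Both sign conventions are flippable.  Trials are summarised over three
endurance-time windows (start / middle / end of the trial, each a short
average of the configured length, clamped to at most one minute).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import keypoints
from .anthropometry import BodyModel, segment_com
from .mocap import Pose3D

WINDOW_LABELS = ("start", "middle", "end")


@dataclass
class CoMSample:
    """Per-frame CoM and pelvis-relative displacement (cm)."""

    time: float
    com: Optional[np.ndarray]           # (3,) cm, None when missing
    pelvis: Optional[np.ndarray]        # (3,) cm
    d_y: float                          # cm, downward-positive by default
    d_z: float                          # cm, posterior-positive by default
    missing_keypoints: tuple[int, ...] = ()

    @property
    def is_valid(self) -> bool:
        return self.com is not None and np.isfinite(self.d_y) and np.isfinite(self.d_z)


@dataclass
class WindowStats:
    label: str
    t_start: float
    t_end: float
    mean_d_y: float
    mean_d_z: float
    n_frames: int


@dataclass
class TrialSummary:
    participant: str
    sex: str
    gravity: str                  # "1/6g" or "1g"
    task: str                     # "static" or "dynamic"
    load_kg: float
    et_min: float
    windows: dict[str, WindowStats] = field(default_factory=dict)


def displacement_axes(
    com,
    pelvis,
    down_positive: bool = True,
    posterior_positive: bool = True,
) -> tuple[float, float]:
    """Pelvis-relative displacement (dY, dZ) in cm.

    With the default conventions a CoM below the pelvis gives dY > 0 and a
    CoM behind the pelvis gives dZ > 0, so that the downward shift and the
    backward tilt reported for increasing gravity appear as positive
    regression coefficients.
    """
    c = np.asarray(com, dtype=float)
    p = np.asarray(pelvis, dtype=float)
    if not (np.all(np.isfinite(c)) and np.all(np.isfinite(p))):
        raise ValueError("displacement_axes requires finite inputs")
    d_y = p[1] - c[1]
    d_z = p[2] - c[2]
    if not down_positive:
        d_y = -d_y
    if not posterior_positive:
        d_z = -d_z
    return float(d_y), float(d_z)


def body_com(
    pose: Pose3D,
    model: BodyModel,
    pelvis_index: int = keypoints.PELVIS,
    down_positive: bool = True,
    posterior_positive: bool = True,
) -> CoMSample:
    """Whole-body CoM of one frame under the segmental model.

    A frame missing any keypoint the model requires (or the pelvis) is
    returned as a missing sample with the offending keypoints listed; it is
    never silently interpolated.
    """
    required = set(model.required_keypoints())
    required.add(pelvis_index)
    missing = tuple(sorted(k for k in required if not pose.valid[k]))
    if missing:
        return CoMSample(pose.time, None, None, float("nan"), float("nan"), missing)
    num = np.zeros(3)
    M = 0.0
    for seg in model.segments:
        m = model.segment_mass(seg)
        c = segment_com(pose.xyz[seg.proximal_joint], pose.xyz[seg.distal_joint], seg.k)
        num += m * c
        M += m
    com = num / M
    pelvis = pose.xyz[pelvis_index].astype(float)
    d_y, d_z = displacement_axes(com, pelvis, down_positive, posterior_positive)
    return CoMSample(pose.time, com, pelvis, d_y, d_z)


def et_windows(
    samples: Sequence[CoMSample],
    et_min: float,
    window_s: float = 5.0,
    max_window_s: float = 60.0,
    span_tolerance_s: float = 60.0,
) -> dict[str, WindowStats]:
    """Start / middle / end window means of dY and dZ.

    The window length w is ``window_s`` clamped to ``max_window_s`` and to
    the trial duration.  Windows are ``[0, w)``, ``[ET/2 - w/2, ET/2 + w/2)``
    and ``[ET - w, ET)`` (seconds, half-open so that a trial sampled at the
    frame rate contributes exactly ``w * rate`` frames per window); means
    use valid samples only; an empty window is reported with
    ``n_frames = 0`` and NaN means plus a warning.
    """
    if not et_min > 0:
        raise ValueError("ET must be > 0")
    et_s = et_min * 60.0
    ordered = sorted(samples, key=lambda s: s.time)
    if ordered:
        span = ordered[-1].time
        if span > et_s + span_tolerance_s:
            raise ValueError(
                f"sample span {span:.1f}s exceeds ET {et_s:.1f}s by more than "
                f"the {span_tolerance_s:.0f}s tolerance"
            )
    w = min(max(window_s, 0.0), max_window_s, et_s)
    bounds = {
        "start": (0.0, w),
        "middle": (et_s / 2.0 - w / 2.0, et_s / 2.0 + w / 2.0),
        "end": (et_s - w, et_s),
    }
    out: dict[str, WindowStats] = {}
    eps = 1e-9
    for label in WINDOW_LABELS:
        a, b = bounds[label]
        vals = [
            (s.d_y, s.d_z)
            for s in ordered
            if s.is_valid and (a - eps) <= s.time < (b - eps)
        ]
        if vals:
            arr = np.asarray(vals)
            out[label] = WindowStats(label, a, b, float(arr[:, 0].mean()),
                                     float(arr[:, 1].mean()), len(vals))
        else:
            warnings.warn(f"ET window {label!r} [{a:.1f}, {b:.1f}]s contains no valid samples")
            out[label] = WindowStats(label, a, b, float("nan"), float("nan"), 0)
    return out


def summarize_trial(
    samples: Sequence[CoMSample],
    participant: str,
    sex: str,
    gravity: str,
    task: str,
    load_kg: float,
    et_min: float,
    window_s: float = 5.0,
    max_window_s: float = 60.0,
) -> TrialSummary:
    windows = et_windows(samples, et_min, window_s=window_s, max_window_s=max_window_s)
    return TrialSummary(
        participant=participant, sex=sex, gravity=gravity, task=task,
        load_kg=load_kg, et_min=et_min, windows=windows,
    )
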