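"""Synthetic seated-task studies: cohorts, kinematics, multi-camera JSON.

The generator produces complete synthetic studies so that every pipeline
stage (keypoint JSON parsing, triangulation, segmental CoM, ET windows,
OLS) can be exercised against known ground truth without any download:

* a **cohort** drawn from sex-specific truncated normals (heights, masses,
  with segment lengths and volumes scaled deterministically from them);
* per-trial **window targets** for the pelvis-relative displacement, drawn
  from the configured linear model
  ``mu = offset + constant + beta_g I(1g) + beta_task I(dynamic)`` plus
  Gaussian residual noise, per axis;
* a seated 25-keypoint **skeleton** posed so that the segmental CoM of the
  posed skeleton reproduces each window target exactly.  The pose has two
  solved degrees of freedom: a trunk-flexion (slouch) scale that sets the
  CoM distance from the hip (1-D root find) and a torso pitch that sets its
  direction (closed form).  Arm elevation is driven by the task: a static
  outstretched hold, or a forearm oscillation whose hand speed stays below
  the configured slow-movement maximum;
* **rendered views**: each camera of a surrounding rig projects every
  frame's keypoints, Gaussian pixel noise and confidence dropout are
  applied, and frames are written in the reader's JSON dialect.

Targets that residual noise pushes outside the skeleton's reachable CoM
set are either reported as an error (single-trial default) or projected
onto the reachable set, preferentially preserving the proximodistal
coordinate (study-level default); realized values are bookkept in the
ground truth either way.

Everything is deterministic under a fixed seed; per-trial random streams
are spawned from the master seed so regenerating a subset is stable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import j0

from . import keypoints
from .anthropometry import BodyModel, default_segment_table
from .com import CoMSample, body_com, displacement_axes
from .mocap import CameraModel, Pose3D, save_calibration, write_openpose_frame

GRAVITIES = ("1/6g", "1g")
TASKS = ("static", "dynamic")
AXES = ("dY", "dZ")

#: keypoints rotated about the hip by the torso pitch (everything above the
#: pelvis); hips and legs stay seated.
_UPPER = (0, 1, 2, 3, 4, 5, 6, 7, 15, 16, 17, 18)


@dataclass(frozen=True)
class EffectParams:
    """Linear-model parameters for one (sex, axis) cell, in cm.

    ``offset`` is a posture baseline: the generator realises the target
    ``offset + constant + beta_g I(1g) + beta_task I(dynamic) + noise``
    geometrically, so the offset shifts only the recovered intercept, never
    the gravity/task coefficients or the residual SD.  Defaults place each
    sex's targets in a region the seated template can express.
    """

    constant: float
    beta_g: float
    beta_task: float
    residual_sd: float
    offset: float = 0.0

    def mean(self, g_level: int, task: int) -> float:
        return self.offset + self.constant + self.beta_g * g_level + self.beta_task * task


def _default_effects() -> dict[tuple[str, str], EffectParams]:
    return {
        ("male", "dY"): EffectParams(-8.47, 17.06, 3.17, 8.45, offset=-1.6),
        ("male", "dZ"): EffectParams(6.67, -1.45, -2.17, 8.01, offset=-35.0),
        ("female", "dY"): EffectParams(5.70, 5.87, -0.94, 2.11, offset=-37.0),
        ("female", "dZ"): EffectParams(-3.77, 6.02, 0.44, 5.26, offset=0.5),
    }


def _default_anthro() -> dict[str, dict[str, float]]:
    # sex-stratified means/SDs with cohort-wide truncation bounds
    return {
        "male": {
            "height_mean": 1.83, "height_sd": 0.07,
            "mass_mean": 82.92, "mass_sd": 13.02,
            "upper_arm_m": 0.35, "forearm_m": 0.30,
            "torso_vol_dm3": 44.71, "upper_arm_vol_dm3": 2.70,
            "forearm_vol_dm3": 1.37,
        },
        "female": {
            "height_mean": 1.66, "height_sd": 0.06,
            "mass_mean": 56.19, "mass_sd": 5.95,
            "upper_arm_m": 0.32, "forearm_m": 0.25,
            "torso_vol_dm3": 27.00, "upper_arm_vol_dm3": 1.48,
            "forearm_vol_dm3": 0.72,
        },
        "bounds": {
            "height_min": 1.54, "height_max": 1.95,
            "mass_min": 43.8, "mass_max": 114.10,
        },
    }


def _default_et_means() -> dict[tuple[str, str, str, float], float]:
    """Mean endurance times (min) keyed by (sex, task, gravity, load_kg)."""
    tbl = {
        ("static", "1g", 1.0): (1.67, 0.95),
        ("static", "1g", 3.0): (0.85, 0.34),
        ("static", "1/6g", 1.0): (7.73, 6.21),
        ("static", "1/6g", 3.0): (2.65, 0.65),
        ("dynamic", "1g", 1.0): (1.30, 0.80),
        ("dynamic", "1g", 3.0): (0.79, 0.35),
        ("dynamic", "1/6g", 1.0): (14.93, 9.34),
        ("dynamic", "1/6g", 3.0): (2.16, 0.82),
    }
    out: dict[tuple[str, str, str, float], float] = {}
    for (task, grav, load), (m, f) in tbl.items():
        out[("male", task, grav, load)] = m
        out[("female", task, grav, load)] = f
    return out


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generator (all units documented)."""

    n_male: int = 18
    n_female: int = 14
    #: analysis rows per sex (3 window rows per trial; the last trial of a
    #: sex may contribute fewer rows when n is not divisible by 3)
    n_rows: dict[str, int] = field(default_factory=lambda: {"male": 114, "female": 56})
    anthro: dict = field(default_factory=_default_anthro)
    effects: dict[tuple[str, str], EffectParams] = field(default_factory=_default_effects)
    et_means_min: dict = field(default_factory=_default_et_means)
    et_cv: float = 0.3
    loads_kg: tuple[float, ...] = (1.0, 3.0)
    # camera rig: three cameras on a 2 m circle, 120 deg apart
    n_cameras: int = 3
    camera_radius_cm: float = 200.0
    camera_height_cm: float = 100.0
    focal_px: float = 1100.0
    image_size: tuple[int, int] = (1920, 1080)
    fps: float = 30.0
    pixel_noise_sd: float = 1.0
    dropout_p: float = 0.02
    # trial kinematics
    window_s: float = 5.0
    max_window_s: float = 60.0
    hip_height_cm: float = 75.0
    pitch_jitter_deg: float = 0.05
    max_hand_speed_cm_s: float = 47.0
    hand_speed_margin: float = 0.9
    rom_deg: float = 60.0             # peak-to-peak forearm oscillation
    slouch_bounds: tuple[float, float] = (0.45, 1.15)

    def __post_init__(self) -> None:
        if self.et_cv < 0 or self.pixel_noise_sd < 0:
            raise ValueError("spread parameters must be >= 0")
        if not 0.0 <= self.dropout_p <= 1.0:
            raise ValueError("dropout_p must be in [0, 1]")
        for s in ("male", "female"):
            sd_keys = ("height_sd", "mass_sd")
            if any(self.anthro[s][k] < 0 for k in sd_keys):
                raise ValueError("anthropometric SDs must be >= 0")


@dataclass
class Participant:
    pid: str
    sex: str
    height_m: float
    mass_kg: float
    upper_arm_m: float
    forearm_m: float
    volumes_dm3: dict[str, float]


@dataclass(frozen=True)
class ArmPose:
    """Sagittal-plane arm directions as (dy, dz) vectors, proximal to distal.

    Unit vectors for real poses; the dynamic-task *effective* pose uses a
    shortened forearm direction equal to the oscillation's time average.
    """

    u_r: tuple[float, float]
    f_r: tuple[float, float]
    u_l: tuple[float, float] = (-1.0, 0.0)
    f_l: tuple[float, float] = (-1.0, 0.0)


_ARM_STATIC = ArmPose(u_r=(0.0, 1.0), f_r=(0.0, 1.0))


def _arm_dynamic(phi: float) -> ArmPose:
    return ArmPose(u_r=(0.0, 1.0), f_r=(math.sin(phi), math.cos(phi)))


def _arm_dynamic_effective(amp_rad: float) -> ArmPose:
    # time average of (sin phi, cos phi) over phi = A sin(w t): (0, J0(A))
    return ArmPose(u_r=(0.0, 1.0), f_r=(0.0, float(j0(amp_rad))))


class PoseTargetError(ValueError):
    """Raised when a window target lies outside the template's reachable set."""

    def __init__(self, msg: str, target_cm: tuple[float, float],
                 reachable_radius_cm: tuple[float, float]):
        super().__init__(msg)
        self.target_cm = target_cm
        self.reachable_radius_cm = reachable_radius_cm


@dataclass
class WindowTruth:
    label: str
    t_start: float
    t_end: float
    d_y_target: float
    d_z_target: float
    d_y_realized: float
    d_z_realized: float
    clipped: bool
    pitch_rad: float
    slouch: float


@dataclass
class SyntheticTrial:
    trial_id: str
    participant: Participant
    gravity: str
    task: str
    load_kg: float
    et_min: float
    windows: list[WindowTruth]
    #: (frame_index, time_s, (25, 3) world keypoints cm), windows only
    frames: list[tuple[int, float, np.ndarray]]
    fps: float
    hip_height_cm: float

    def window_pose(self, label: str, config: "GeneratorConfig") -> Pose3D:
        """Anchor pose of one window (effective arm, no jitter).

        Feeding this pose through the segmental CoM recovers the window's
        realized displacement to numerical precision.
        """
        w = next(x for x in self.windows if x.label == label)
        arms = _task_arm_effective(self.task, config)
        kp = seated_keypoints(self.participant, w.pitch_rad, w.slouch, arms,
                              hip_height_cm=self.hip_height_cm)
        n = keypoints.N_KEYPOINTS
        return Pose3D(0, w.t_start, kp, np.ones(n, bool), np.zeros(n))


# -- cohort ----------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, max_tries: int = 1000) -> float:
    if not lo <= hi:
        raise ValueError(f"impossible truncation bounds [{lo}, {hi}]")
    if sd == 0:
        if not lo <= mean <= hi:
            raise ValueError("degenerate draw: mean outside truncation bounds")
        return mean
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ValueError(
        f"truncation bounds [{lo}, {hi}] too far from N({mean}, {sd}); "
        "no draw accepted"
    )


def generate_cohort(config: GeneratorConfig,
                    rng: np.random.Generator) -> list[Participant]:
    """Draw the participant cohort.

    Heights and masses are sex-specific truncated normals; segment lengths
    scale with height and segment volumes with mass (deterministically), so
    a participant's skeleton and buoyancy are mutually consistent.
    """
    if config.n_male + config.n_female < 1:
        raise ValueError("cohort must contain at least one participant")
    b = config.anthro["bounds"]
    out: list[Participant] = []
    for sex, n in (("male", config.n_male), ("female", config.n_female)):
        a = config.anthro[sex]
        for i in range(n):
            h = _truncated_normal(rng, a["height_mean"], a["height_sd"],
                                  b["height_min"], b["height_max"])
            m = _truncated_normal(rng, a["mass_mean"], a["mass_sd"],
                                  b["mass_min"], b["mass_max"])
            h_scale = h / a["height_mean"]
            m_scale = m / a["mass_mean"]
            out.append(Participant(
                pid=f"{sex[0].upper()}{i + 1:02d}",
                sex=sex,
                height_m=h,
                mass_kg=m,
                upper_arm_m=a["upper_arm_m"] * h_scale,
                forearm_m=a["forearm_m"] * h_scale,
                volumes_dm3={
                    "torso": a["torso_vol_dm3"] * m_scale,
                    "upper_arm": a["upper_arm_vol_dm3"] * m_scale,
                    "forearm": a["forearm_vol_dm3"] * m_scale,
                },
            ))
    return out


# -- skeleton template -----------------------------------------------------

def seated_keypoints(p: Participant, pitch_rad: float, slouch: float,
                     arms: ArmPose, hip_height_cm: float = 75.0) -> np.ndarray:
    """World keypoints (25, 3) cm of the seated template.

    The subject sits at the origin facing +Z (anterior), Y up, X to the
    subject's left; the pelvis (MidHip) is at (0, hip_height, 0).  ``slouch``
    scales the hip-to-shoulder trunk length (spinal flexion surrogate);
    ``pitch_rad`` rotates everything above the pelvis forward (+) about the
    mediolateral axis through the hip.
    """
    H = p.height_m * 100.0
    T = slouch * 0.288 * H                      # hip -> shoulder line
    l_ua = p.upper_arm_m * 100.0
    l_fa = p.forearm_m * 100.0
    sh_x = 0.115 * H
    kp = np.zeros((keypoints.N_KEYPOINTS, 3))   # local, relative to MidHip

    kp[keypoints.NECK] = (0.0, T, 0.0)
    kp[keypoints.NOSE] = (0.0, T + 0.11 * H, 0.02 * H)
    kp[keypoints.R_EYE] = (-0.03 * H, T + 0.115 * H, 0.03 * H)
    kp[keypoints.L_EYE] = (0.03 * H, T + 0.115 * H, 0.03 * H)
    kp[keypoints.R_EAR] = (-0.06 * H, T + 0.105 * H, 0.0)
    kp[keypoints.L_EAR] = (0.06 * H, T + 0.105 * H, 0.0)

    for sh_i, el_i, wr_i, sx, u, f in (
        (keypoints.R_SHOULDER, keypoints.R_ELBOW, keypoints.R_WRIST, -sh_x,
         arms.u_r, arms.f_r),
        (keypoints.L_SHOULDER, keypoints.L_ELBOW, keypoints.L_WRIST, +sh_x,
         arms.u_l, arms.f_l),
    ):
        sh = np.array([sx, T, 0.0])
        el = sh + l_ua * np.array([0.0, u[0], u[1]])
        wr = el + l_fa * np.array([0.0, f[0], f[1]])
        kp[sh_i], kp[el_i], kp[wr_i] = sh, el, wr

    hip_x = 0.05 * H
    kp[keypoints.MID_HIP] = (0.0, 0.0, 0.0)
    for hp, kn, an, bt, st, he, sx in (
        (keypoints.R_HIP, keypoints.R_KNEE, keypoints.R_ANKLE,
         keypoints.R_BIG_TOE, keypoints.R_SMALL_TOE, keypoints.R_HEEL, -hip_x),
        (keypoints.L_HIP, keypoints.L_KNEE, keypoints.L_ANKLE,
         keypoints.L_BIG_TOE, keypoints.L_SMALL_TOE, keypoints.L_HEEL, +hip_x),
    ):
        kp[hp] = (sx, 0.0, 0.0)
        kp[kn] = (sx, 0.0, 0.245 * H)
        kp[an] = (sx, -0.246 * H, 0.245 * H)
        kp[bt] = (sx, -0.285 * H, 0.315 * H)
        kp[st] = (sx * 1.3, -0.285 * H, 0.300 * H)
        kp[he] = (sx, -0.285 * H, 0.225 * H)

    c, s = math.cos(pitch_rad), math.sin(pitch_rad)
    upper = kp[list(_UPPER)]
    y, z = upper[:, 1].copy(), upper[:, 2].copy()
    upper[:, 1] = c * y - s * z
    upper[:, 2] = s * y + c * z
    kp[list(_UPPER)] = upper

    kp[:, 1] += hip_height_cm
    return kp


def _local_upper_com(model: BodyModel, p: Participant, slouch: float,
                     arms: ArmPose) -> np.ndarray:
    """Modeled-segment CoM relative to the hip, unpitched body frame (cm)."""
    kp = seated_keypoints(p, 0.0, slouch, arms, hip_height_cm=0.0)
    num = np.zeros(3)
    M = 0.0
    for seg in model.segments:
        m = model.segment_mass(seg)
        a, b = kp[seg.proximal_joint], kp[seg.distal_joint]
        num += m * (a + seg.k * (b - a))
        M += m
    return num / M


def _task_arm_effective(task: str, config: GeneratorConfig) -> ArmPose:
    if task == "static":
        return _ARM_STATIC
    return _arm_dynamic_effective(math.radians(config.rom_deg) / 2.0)


def reachable_radius(p: Participant, task: str,
                     config: GeneratorConfig) -> tuple[float, float]:
    """CoM distance from the hip (cm) attainable by the slouch DOF."""
    model = default_segment_table(p.sex)
    arms = _task_arm_effective(task, config)
    lo, hi = config.slouch_bounds
    r = [float(np.linalg.norm(_local_upper_com(model, p, s, arms)[1:]))
         for s in (lo, hi)]
    return min(r), max(r)


def _solve_pose(
    target_yz: tuple[float, float],
    p: Participant,
    task: str,
    config: GeneratorConfig,
    on_unreachable: str = "error",
) -> tuple[float, float, tuple[float, float], bool]:
    """Solve (slouch, pitch) so the posed CoM hits ``target_yz`` (hip-relative).

    Returns ``(slouch, pitch, realized_yz, clipped)``.  The slouch scale is
    found by a 1-D root find on the CoM radius; the pitch then aligns the
    CoM direction in closed form.  Unreachable targets either raise
    :class:`PoseTargetError` or are projected onto the reachable annulus
    (``on_unreachable="clip"``), preserving the proximodistal coordinate
    where possible.
    """
    model = default_segment_table(p.sex)
    arms = _task_arm_effective(task, config)
    lo, hi = config.slouch_bounds

    def com_yz(s: float) -> np.ndarray:
        return _local_upper_com(model, p, s, arms)[1:]

    r_lo = float(np.linalg.norm(com_yz(lo)))
    r_hi = float(np.linalg.norm(com_yz(hi)))
    if r_lo > r_hi:
        r_lo, r_hi = r_hi, r_lo
    v = np.asarray(target_yz, dtype=float)
    r_t = float(np.linalg.norm(v))
    clipped = False
    if not r_lo <= r_t <= r_hi:
        if on_unreachable == "error":
            raise PoseTargetError(
                f"target CoM offset {tuple(np.round(v, 2))} cm has radius "
                f"{r_t:.2f} cm outside the template's reachable "
                f"[{r_lo:.2f}, {r_hi:.2f}] cm",
                target_cm=(float(v[0]), float(v[1])),
                reachable_radius_cm=(r_lo, r_hi),
            )
        if on_unreachable != "clip":
            raise ValueError("on_unreachable must be 'error' or 'clip'")
        clipped = True
        vy, vz = float(v[0]), float(v[1])
        zsign = 1.0 if vz >= 0 else -1.0
        # project onto the annulus with a small interior margin so the
        # radius root-find below always brackets
        r_in = r_hi * (1.0 - 1e-9)
        r_out = r_lo * (1.0 + 1e-9)
        if r_t > r_hi:
            if abs(vy) < 0.999 * r_in:
                v = np.array([vy, zsign * math.sqrt(r_in**2 - vy**2)])
            else:
                v = v * (r_in / r_t)
        else:  # r_t < r_lo; |vy| <= r_t < r_lo so the y-preserving point exists
            v = np.array([vy, zsign * math.sqrt(r_out**2 - vy**2)])
        r_t = float(np.linalg.norm(v))
    r_t = min(max(r_t, r_lo * (1.0 + 1e-12)), r_hi * (1.0 - 1e-12))

    s_sol = brentq(lambda s: float(np.linalg.norm(com_yz(s))) - r_t, lo, hi,
                   xtol=1e-12, rtol=8.9e-16)
    c = com_yz(s_sol)
    pitch = math.atan2(v[1], v[0]) - math.atan2(c[1], c[0])
    # wrap to (-pi, pi] for interpolation friendliness
    pitch = math.atan2(math.sin(pitch), math.cos(pitch))
    # realized CoM offset of the solved pose (exactly what the posed
    # skeleton measures back; equals v to solver precision)
    cp, sp = math.cos(pitch), math.sin(pitch)
    v_real = (cp * c[0] - sp * c[1], sp * c[0] + cp * c[1])
    return float(s_sol), float(pitch), (float(v_real[0]), float(v_real[1])), clipped


# -- trials ----------------------------------------------------------------

def _window_bounds(et_min: float, window_s: float,
                   max_window_s: float) -> list[tuple[str, float, float]]:
    et_s = et_min * 60.0
    w = min(max(window_s, 0.0), max_window_s, et_s)
    return [
        ("start", 0.0, w),
        ("middle", et_s / 2.0 - w / 2.0, et_s / 2.0 + w / 2.0),
        ("end", et_s - w, et_s),
    ]


def _draw_et_min(config: GeneratorConfig, sex: str, task: str, gravity: str,
                 load: float, rng: np.random.Generator) -> float:
    mean = config.et_means_min[(sex, task, gravity, load)]
    cv = config.et_cv
    if cv == 0:
        return float(mean)
    sigma = math.sqrt(math.log1p(cv * cv))
    mu = math.log(mean) - 0.5 * sigma * sigma
    return float(rng.lognormal(mu, sigma))


def generate_trial(
    participant: Participant,
    gravity: str,
    task: str,
    load_kg: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
    trial_id: Optional[str] = None,
    on_unreachable: str = "error",
) -> SyntheticTrial:
    """Generate one trial: targets, solved poses, window frame sequences.

    Frames are generated only inside the three ET windows (the regression
    consumes window means; intermediate frames carry no information).  The
    dynamic task oscillates the loaded forearm with the wrist speed capped
    at ``hand_speed_margin * max_hand_speed_cm_s``; the pose is solved with
    the oscillation's time-averaged arm so window means reproduce targets.
    """
    if gravity not in GRAVITIES or task not in TASKS:
        raise ValueError(f"invalid factor levels ({gravity!r}, {task!r})")
    sex = participant.sex
    g_ind = 1 if gravity == "1g" else 0
    t_ind = 1 if task == "dynamic" else 0
    et_min = _draw_et_min(config, sex, task, gravity, load_kg, rng)
    ep_y = config.effects[(sex, "dY")]
    ep_z = config.effects[(sex, "dZ")]

    amp = math.radians(config.rom_deg) / 2.0
    l_fa_cm = participant.forearm_m * 100.0
    omega = (config.hand_speed_margin * config.max_hand_speed_cm_s
             / (l_fa_cm * amp)) if task == "dynamic" else 0.0
    jitter_rad = math.radians(config.pitch_jitter_deg)

    windows: list[WindowTruth] = []
    frames: list[tuple[int, float, np.ndarray]] = []
    for label, a, b in _window_bounds(et_min, config.window_s, config.max_window_s):
        d_y_t = ep_y.mean(g_ind, t_ind) + rng.normal() * ep_y.residual_sd
        d_z_t = ep_z.mean(g_ind, t_ind) + rng.normal() * ep_z.residual_sd
        # dY = pelvis_y - com_y  =>  hip-relative CoM target is (-dY, -dZ)
        s_sol, pitch, v_real, clipped = _solve_pose(
            (-d_y_t, -d_z_t), participant, task, config, on_unreachable)
        windows.append(WindowTruth(
            label=label, t_start=a, t_end=b,
            d_y_target=d_y_t, d_z_target=d_z_t,
            d_y_realized=-v_real[0], d_z_realized=-v_real[1],
            clipped=clipped, pitch_rad=pitch, slouch=s_sol,
        ))
        i0 = math.ceil(a * config.fps - 1e-9)
        i1 = math.ceil(b * config.fps - 1e-9)      # half-open [a, b)
        for i in range(i0, i1):
            t = i / config.fps
            if task == "dynamic":
                arms = _arm_dynamic(amp * math.sin(omega * t))
            else:
                arms = _ARM_STATIC
            p_jit = pitch + (rng.normal() * jitter_rad if jitter_rad > 0 else 0.0)
            kp = seated_keypoints(participant, p_jit, s_sol, arms,
                                  hip_height_cm=config.hip_height_cm)
            frames.append((i, t, kp))

    tid = trial_id or f"{participant.pid}_{gravity.replace('/', '_')}_{task}_{load_kg:g}kg"
    return SyntheticTrial(
        trial_id=tid, participant=participant, gravity=gravity, task=task,
        load_kg=load_kg, et_min=et_min, windows=windows, frames=frames,
        fps=config.fps, hip_height_cm=config.hip_height_cm,
    )


# -- rendering -------------------------------------------------------------

def default_camera_rig(config: GeneratorConfig) -> dict[str, CameraModel]:
    """Cameras on a circle around the seat, equally spaced in azimuth."""
    target = (0.0, config.hip_height_cm + 20.0, 5.0)
    rig: dict[str, CameraModel] = {}
    for i in range(config.n_cameras):
        az = 2.0 * math.pi * i / config.n_cameras
        pos = (config.camera_radius_cm * math.sin(az),
               config.camera_height_cm,
               config.camera_radius_cm * math.cos(az))
        rig[f"cam{i + 1}"] = CameraModel.looking_at(
            pos, target, focal_px=config.focal_px, image_size=config.image_size)
    return rig


def render_views(
    trial: SyntheticTrial,
    cameras: dict[str, CameraModel],
    out_dir,
    rng: np.random.Generator,
    pixel_noise_sd: float = 1.0,
    dropout_p: float = 0.02,
) -> None:
    """Project every trial frame through every camera and write JSON files.

    Output layout: ``out_dir/<cam>/frame_%06d.json``.  Gaussian pixel noise
    is added; keypoints are dropped (confidence zeroed) with probability
    ``dropout_p``; a keypoint behind a camera is dropped with a warning.
    """
    out = Path(out_dir)
    n = keypoints.N_KEYPOINTS
    warned_behind = set()
    for name in sorted(cameras):
        cam = cameras[name]
        cam_dir = out / name
        for idx, _t, kp3 in trial.frames:
            rec = np.zeros((n, 3))
            depth_ok = (kp3 @ cam.R.T + cam.t)[:, 2] > 0
            if not np.all(depth_ok) and name not in warned_behind:
                warnings.warn(f"{name}: keypoints behind the camera were dropped")
                warned_behind.add(name)
            if np.any(depth_ok):
                px = cam.project(kp3[depth_ok])
                px = px + rng.normal(size=px.shape) * pixel_noise_sd
                conf = rng.uniform(0.5, 0.95, size=px.shape[0])
                keep = rng.random(px.shape[0]) >= dropout_p
                rows = np.flatnonzero(depth_ok)[keep]
                rec[rows, :2] = px[keep]
                rec[rows, 2] = conf[keep]
            write_openpose_frame(cam_dir / f"frame_{idx:06d}.json", rec)


# -- whole studies ---------------------------------------------------------

def _trial_plan(config: GeneratorConfig, sex: str,
                cohort: list[Participant]) -> list[tuple[Participant, str, str, float]]:
    """Round-robin allocation of trials over (gravity, task, load) cells."""
    n_rows = config.n_rows[sex]
    n_trials = math.ceil(n_rows / 3)
    cells = [(g, t, l) for g in GRAVITIES for t in TASKS for l in config.loads_kg]
    people = [p for p in cohort if p.sex == sex]
    if not people:
        raise ValueError(f"cohort contains no {sex} participants")
    plan = []
    for i in range(n_trials):
        g, t, l = cells[i % len(cells)]
        plan.append((people[i % len(people)], g, t, l))
    return plan


def generate_study(config: GeneratorConfig, out_dir, seed: int) -> pd.DataFrame:
    """Emit a complete synthetic study tree and return the truth table.

    Layout::

        out_dir/
          calib.yaml  study.yaml  meta.csv  truth.csv
          <trial_id>/cam{1..3}/frame_%06d.json

    Per-trial random streams are spawned from ``seed``, so output is
    byte-identical across runs with the same seed and config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    cohort_ss, trials_ss = ss.spawn(2)
    cohort = generate_cohort(config, np.random.default_rng(cohort_ss))

    rig = default_camera_rig(config)
    save_calibration(rig, out / "calib.yaml")
    with open(out / "study.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {"fps": config.fps, "window_s": config.window_s,
             "max_window_s": config.max_window_s,
             "axes": {"dY": "downward positive", "dZ": "posterior positive"}},
            fh, sort_keys=True)

    meta_rows, truth_rows = [], []
    plans = [(s, pl) for s in ("male", "female")
             for pl in [_trial_plan(config, s, cohort)]]
    n_total = sum(len(pl) for _s, pl in plans)
    streams = trials_ss.spawn(n_total)
    k = 0
    for sex, plan in plans:
        for j, (person, grav, task, load) in enumerate(plan):
            gen_ss, render_ss = streams[k].spawn(2)
            k += 1
            tid = f"{sex[0]}{j:03d}_{person.pid}_{grav.replace('/', '_')}_{task}_{load:g}kg"
            trial = generate_trial(
                person, grav, task, load, config,
                np.random.default_rng(gen_ss), trial_id=tid,
                on_unreachable="clip")
            render_views(trial, rig, out / tid, np.random.default_rng(render_ss),
                         pixel_noise_sd=config.pixel_noise_sd,
                         dropout_p=config.dropout_p)
            meta_rows.append({
                "trial_id": tid, "participant": person.pid, "sex": sex,
                "height_m": round(person.height_m, 6),
                "mass_kg": round(person.mass_kg, 6),
                "gravity": grav, "task": task, "load_kg": load,
                "et_min": round(trial.et_min, 6),
            })
            for w in trial.windows:
                truth_rows.append({
                    "trial_id": tid, "window": w.label,
                    "dY_target": round(w.d_y_target, 9),
                    "dZ_target": round(w.d_z_target, 9),
                    "dY_realized": round(w.d_y_realized, 9),
                    "dZ_realized": round(w.d_z_realized, 9),
                    "clipped": int(w.clipped),
                    "pitch_rad": round(w.pitch_rad, 9),
                    "slouch": round(w.slouch, 9),
                })
    meta = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    meta.to_csv(out / "meta.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    return truth


def simulate_measured_rows(
    config: GeneratorConfig,
    sex: str,
    rng: np.random.Generator,
    geometry: bool = True,
) -> pd.DataFrame:
    """Analysis rows for one sex without rendering (replicate-level helper).

    Draws the cohort and window targets exactly as :func:`generate_study`,
    and with ``geometry=True`` realizes each target through the pose solver
    and measures it back through the segmental CoM of the posed skeleton,
    so the geometric stage (including reachability clipping) is part of the
    data-generating process.  ``geometry=False`` returns the pure
    linear-model draws.  Rows are trimmed to ``config.n_rows[sex]``.
    """
    cohort = generate_cohort(config, rng)
    plan = _trial_plan(config, sex, cohort)
    ep_y = config.effects[(sex, "dY")]
    ep_z = config.effects[(sex, "dZ")]
    rows = []
    for j, (person, grav, task, load) in enumerate(plan):
        g_ind = 1 if grav == "1g" else 0
        t_ind = 1 if task == "dynamic" else 0
        for label in ("start", "middle", "end"):
            d_y = ep_y.mean(g_ind, t_ind) + rng.normal() * ep_y.residual_sd
            d_z = ep_z.mean(g_ind, t_ind) + rng.normal() * ep_z.residual_sd
            if geometry:
                s_sol, pitch, v_real, _cl = _solve_pose(
                    (-d_y, -d_z), person, task, config, on_unreachable="clip")
                arms = _task_arm_effective(task, config)
                kp = seated_keypoints(person, pitch, s_sol, arms,
                                      hip_height_cm=config.hip_height_cm)
                n = keypoints.N_KEYPOINTS
                pose = Pose3D(0, 0.0, kp, np.ones(n, bool), np.zeros(n))
                model = default_segment_table(sex, total_mass=person.mass_kg)
                sample = body_com(pose, model)
                d_y, d_z = sample.d_y, sample.d_z
            rows.append({
                "participant": person.pid, "sex": sex, "window": label,
                "g_level": g_ind, "task": t_ind, "gravity": grav,
                "task_name": task, "load_kg": load, "dY": d_y, "dZ": d_z,
            })
    return pd.DataFrame(rows[: config.n_rows[sex]])
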