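"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from lunarcom.mocap import CameraModel
from lunarcom.synthetic import GeneratorConfig, Participant


# -- independent oracles ---------------------------------------------------

def rod_point_masses(p_prox, p_dist, k: float, n: int = 100_000):
    """Discretize a segment into point masses whose CoM sits at fraction k.

    Two uniform pieces: mass (1-k) spread over [0, k] and mass k over
    [k, 1] of the segment parameter u; the combined CoM is exactly at u=k.
    Returns (positions (n,3), weights (n,)).  Independent of segment_com.
    """
    p = np.asarray(p_prox, float)
    q = np.asarray(p_dist, float)
    if k <= 0.0 or k >= 1.0:
        # end-point cases: a single point mass at the end
        u = np.array([k])
        return p + u[:, None] * (q - p), np.array([1.0])
    n1 = n // 2
    n2 = n - n1
    u1 = (np.arange(n1) + 0.5) / n1 * k            # midpoints on [0, k]
    u2 = k + (np.arange(n2) + 0.5) / n2 * (1 - k)  # midpoints on [k, 1]
    u = np.concatenate([u1, u2])
    w = np.concatenate([np.full(n1, (1 - k) / n1), np.full(n2, k / n2)])
    return p + u[:, None] * (q - p), w


def brute_force_body_com(pose_xyz, segments, masses, n: int = 100_000):
    """Whole-body CoM by summing discretized per-segment point masses.

    ``segments`` is a list of (prox_idx, dist_idx, k); ``masses`` the
    per-segment masses (kg).  Used as the oracle for the segmental formula.
    """
    num = np.zeros(3)
    tot = 0.0
    for (i, j, k), m in zip(segments, masses):
        pts, w = rod_point_masses(pose_xyz[i], pose_xyz[j], k, n)
        num += m * (w @ pts)
        tot += m
    return num / tot


def projection_oracle(cam: CameraModel, point):
    """Pinhole projection by explicit homogeneous 3x4 matrix multiplication."""
    X = np.append(np.asarray(point, float), 1.0)
    x = cam.projection_matrix @ X
    return x[:2] / x[2]


# -- fixtures --------------------------------------------------------------

@pytest.fixture
def three_camera_rig():
    """Three synthetic cameras on a 2 m circle around a seated subject."""
    target = (0.0, 95.0, 5.0)
    cams = []
    for i in range(3):
        az = 2.0 * math.pi * i / 3.0
        pos = (200.0 * math.sin(az), 100.0, 200.0 * math.cos(az))
        cams.append(CameraModel.looking_at(pos, target, focal_px=1100.0,
                                           image_size=(1920, 1080)))
    return cams


@pytest.fixture
def default_config():
    return GeneratorConfig()


@pytest.fixture
def male_participant():
    return Participant(
        pid="M01", sex="male", height_m=1.83, mass_kg=82.92,
        upper_arm_m=0.35, forearm_m=0.30,
        volumes_dm3={"torso": 44.71, "upper_arm": 2.70, "forearm": 1.37},
    )


@pytest.fixture
def female_participant():
    return Participant(
        pid="F01", sex="female", height_m=1.66, mass_kg=56.19,
        upper_arm_m=0.32, forearm_m=0.25,
        volumes_dm3={"torso": 27.00, "upper_arm": 1.48, "forearm": 0.72},
    )
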