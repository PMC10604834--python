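"""Camera models, projection, DLT triangulation, keypoint JSON I/O and PCK.

Coordinate conventions (documented once, used everywhere):

* world frame: right-handed, **X** mediolateral, **Y** up (proximodistal),
  **Z** anterior (anterior-posterior); units **cm**;
* camera frame: +Z looks forward, +X right, +Y down (image row direction);
  ``t`` is the world-to-camera translation so that ``X_cam = R @ X_w + t``;
* pixels: origin at the top-left corner, x right, y down.

Triangulation is confidence-weighted linear DLT.  A keypoint observed with
confidence 0 is treated as undetected and never consumed.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from . import keypoints

_ORTHONORMAL_TOL = 1e-9


@dataclass
class CameraModel:
    """Pinhole camera with optional radial distortion (k1, k2)."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    R: np.ndarray                      # (3,3) world -> camera rotation
    t: np.ndarray                      # (3,) world -> camera translation, cm
    dist: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        self.dist = np.asarray(self.dist, dtype=float).reshape(-1)
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image size must be positive")
        err = np.max(np.abs(self.R.T @ self.R - np.eye(3)))
        if err > 1e-6:
            raise ValueError(f"rotation not orthonormal (max |R'R - I| = {err:.3g})")
        # tighten numerically: re-orthonormalise tiny drift
        if err > _ORTHONORMAL_TOL:
            u, _, vt = np.linalg.svd(self.R)
            self.R = u @ vt

    # -- construction -----------------------------------------------------
    @classmethod
    def looking_at(
        cls,
        position,
        target,
        focal_px: float = 1100.0,
        image_size: tuple[int, int] = (1920, 1080),
        up=(0.0, 1.0, 0.0),
        dist: Sequence[float] = (0.0, 0.0),
    ) -> "CameraModel":
        """Camera at ``position`` (world cm) looking at ``target``."""
        pos = np.asarray(position, dtype=float)
        tgt = np.asarray(target, dtype=float)
        fwd = tgt - pos
        n = np.linalg.norm(fwd)
        if n == 0:
            raise ValueError("camera position coincides with target")
        z = fwd / n
        upv = np.asarray(up, dtype=float)
        x = np.cross(z, upv)  # camera +X (right) for Y-up worlds
        nx = np.linalg.norm(x)
        if nx < 1e-12:
            raise ValueError("up vector parallel to viewing direction")
        x /= nx
        y = np.cross(z, x)    # camera +Y points down in a Y-up world
        R = np.stack([x, y, z])            # rows: camera axes in world coords
        t = -R @ pos
        w, h = image_size
        return cls(
            fx=focal_px, fy=focal_px, cx=w / 2.0, cy=h / 2.0,
            width=int(w), height=int(h), R=R, t=t, dist=np.asarray(dist, float),
        )

    # -- geometry ---------------------------------------------------------
    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    @property
    def projection_matrix(self) -> np.ndarray:
        """3x4 matrix P = K [R | t] (valid when distortion is zero)."""
        return self.K @ np.hstack([self.R, self.t[:, None]])

    def has_distortion(self) -> bool:
        return bool(np.any(self.dist != 0.0))

    def _distort(self, xn: np.ndarray) -> np.ndarray:
        if not self.has_distortion():
            return xn
        k1 = self.dist[0]
        k2 = self.dist[1] if self.dist.size > 1 else 0.0
        r2 = np.sum(xn * xn, axis=-1, keepdims=True)
        return xn * (1.0 + k1 * r2 + k2 * r2 * r2)

    def _undistort(self, xd: np.ndarray, iters: int = 8) -> np.ndarray:
        if not self.has_distortion():
            return xd
        k1 = self.dist[0]
        k2 = self.dist[1] if self.dist.size > 1 else 0.0
        xn = xd.copy()
        for _ in range(iters):          # fixed-point inversion of the radial model
            r2 = np.sum(xn * xn, axis=-1, keepdims=True)
            xn = xd / (1.0 + k1 * r2 + k2 * r2 * r2)
        return xn

    def project(self, point) -> np.ndarray:
        """Project world point(s) (cm) to pixel coordinates.

        Accepts a 3-vector or an (N, 3) array; raises on non-positive depth.
        """
        X = np.asarray(point, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        Xc = X @ self.R.T + self.t
        depth = Xc[:, 2]
        if np.any(depth <= 0):
            raise ValueError("point behind camera (non-positive depth)")
        xn = Xc[:, :2] / depth[:, None]
        xn = self._distort(xn)
        px = np.empty_like(xn)
        px[:, 0] = self.fx * xn[:, 0] + self.cx
        px[:, 1] = self.fy * xn[:, 1] + self.cy
        return px[0] if single else px

    def pixel_to_normalized(self, pixel) -> np.ndarray:
        """Pixel -> undistorted normalized image coordinates (x/z, y/z)."""
        p = np.asarray(pixel, dtype=float)
        xn = np.stack(
            [(p[..., 0] - self.cx) / self.fx, (p[..., 1] - self.cy) / self.fy],
            axis=-1,
        )
        return self._undistort(xn)


# -- poses ----------------------------------------------------------------

@dataclass
class Pose2D:
    """One frame of 25 detected 2D keypoints (x px, y px, confidence)."""

    frame_index: int
    keypoints: np.ndarray    # (25, 3)

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        if self.keypoints.shape != (keypoints.N_KEYPOINTS, 3):
            raise ValueError("Pose2D requires a (25, 3) keypoint array")

    @property
    def detected(self) -> np.ndarray:
        return self.keypoints[:, 2] > 0

    @property
    def is_empty(self) -> bool:
        return not bool(np.any(self.detected))

    @classmethod
    def empty(cls, frame_index: int) -> "Pose2D":
        return cls(frame_index, np.zeros((keypoints.N_KEYPOINTS, 3)))


@dataclass
class Pose3D:
    """Triangulated 25-keypoint skeleton for one frame."""

    frame_index: int
    time: float                 # s
    xyz: np.ndarray             # (25, 3) cm
    valid: np.ndarray           # (25,) bool
    reproj_rms: np.ndarray      # (25,) px (nan where invalid)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.reproj_rms = np.asarray(self.reproj_rms, dtype=float)


# -- OpenPose-dialect JSON I/O -------------------------------------------

_FRAME_RE = re.compile(r"(\d+)(?:_keypoints)?\.json$")


def _frame_index_of(path: Path) -> int:
    m = _FRAME_RE.search(path.name)
    if m:
        return int(m.group(1))
    digits = re.findall(r"\d+", path.name)
    if digits:
        return int(digits[-1])
    raise ValueError(f"cannot parse a frame index from file name {path.name!r}")


def _select_person(people: list, prev_hip: Optional[np.ndarray]) -> np.ndarray:
    """Pick one person: nearest hip to the previous frame, else largest bbox."""
    cands = []
    for person in people:
        arr = person.get("pose_keypoints_2d", person.get("pose_keypoints"))
        if arr is None or len(arr) != keypoints.N_KEYPOINTS * 3:
            raise ValueError("person entry lacks a 75-value keypoint array")
        cands.append(np.asarray(arr, dtype=float).reshape(keypoints.N_KEYPOINTS, 3))
    if len(cands) == 1:
        return cands[0]
    if prev_hip is not None:
        dists = []
        for kp in cands:
            hip = kp[keypoints.MID_HIP]
            dists.append(np.hypot(*(hip[:2] - prev_hip)) if hip[2] > 0 else np.inf)
        if np.isfinite(min(dists)):
            return cands[int(np.argmin(dists))]
    areas = []
    for kp in cands:
        det = kp[kp[:, 2] > 0]
        if det.size == 0:
            areas.append(-1.0)
        else:
            areas.append(float(np.ptp(det[:, 0]) * np.ptp(det[:, 1])))
    return cands[int(np.argmax(areas))]


def read_openpose_frames(source) -> list[Pose2D]:
    """Read a per-camera sequence of OpenPose-format JSON frames.

    ``source`` is a directory (all ``*.json`` inside) or an iterable of file
    paths.  Frames are ordered by the index parsed from the file name; a
    frame with zero people is returned as an empty pose; absent indices are
    simply absent (gap frames).
    """
    src = Path(source) if isinstance(source, (str, Path)) else None
    if src is not None:
        if not src.is_dir():
            raise FileNotFoundError(f"not a directory: {src}")
        files = sorted(src.glob("*.json"), key=_frame_index_of)
    else:
        files = sorted((Path(p) for p in source), key=_frame_index_of)
    out: list[Pose2D] = []
    prev_hip: Optional[np.ndarray] = None
    for path in files:
        idx = _frame_index_of(path)
        try:
            with open(path, "r", encoding="utf-8") as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed keypoint JSON in {path}: {exc}") from exc
        people = doc.get("people", [])
        if not people:
            out.append(Pose2D.empty(idx))
            continue
        kp = _select_person(people, prev_hip)
        kp = kp.copy()
        kp[kp[:, 2] <= 0, :] = 0.0      # undetected: x, y are meaningless
        pose = Pose2D(idx, kp)
        hip = kp[keypoints.MID_HIP]
        if hip[2] > 0:
            prev_hip = hip[:2].copy()
        out.append(pose)
    return out


def write_openpose_frame(path, kp: np.ndarray) -> None:
    """Write one frame in the producer's JSON dialect (version 1.4 layout)."""
    kp = np.asarray(kp, dtype=float)
    if kp.shape != (keypoints.N_KEYPOINTS, 3):
        raise ValueError("expected a (25, 3) keypoint array")
    doc = {
        "version": 1.4,
        "people": [
            {"person_id": [-1], "pose_keypoints_2d": [round(float(v), 6) for v in kp.ravel()]}
        ],
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


# -- calibration I/O ------------------------------------------------------

def save_calibration(cameras: dict[str, CameraModel], path) -> None:
    doc = {"cameras": {}}
    for name, cam in cameras.items():
        doc["cameras"][name] = {
            "K": [[cam.fx, 0.0, cam.cx], [0.0, cam.fy, cam.cy], [0.0, 0.0, 1.0]],
            "R": cam.R.tolist(),
            "t": cam.t.tolist(),
            "image_size": [cam.width, cam.height],
            "distortion": cam.dist.tolist(),
        }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_calibration(path) -> dict[str, CameraModel]:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    out: dict[str, CameraModel] = {}
    for name, c in doc["cameras"].items():
        K = np.asarray(c["K"], dtype=float)
        out[name] = CameraModel(
            fx=float(K[0, 0]), fy=float(K[1, 1]), cx=float(K[0, 2]), cy=float(K[1, 2]),
            width=int(c["image_size"][0]), height=int(c["image_size"][1]),
            R=np.asarray(c["R"], float), t=np.asarray(c["t"], float),
            dist=np.asarray(c.get("distortion", [0.0, 0.0]), float),
        )
    return out


# -- triangulation --------------------------------------------------------

def triangulate(
    observations: Sequence[tuple[CameraModel, Sequence[float], float]],
    min_views: int = 2,
) -> tuple[np.ndarray, float, bool]:
    """Confidence-weighted linear (DLT) triangulation of one point.

    ``observations`` is a sequence of ``(camera, (x_px, y_px), confidence)``.
    Returns ``(point_cm, reprojection_rms_px, valid)``.  Fewer than
    ``min_views`` positive-confidence observations, or a degenerate
    (rank-deficient) system, yields ``valid=False`` rather than an exception.
    The solution is invariant to the observation order.
    """
    used = [(cam, np.asarray(px, float), float(c)) for cam, px, c in observations if c > 0]
    nan3 = np.full(3, np.nan)
    if len(used) < min_views:
        return nan3, float("nan"), False
    rows = []
    for cam, px, conf in used:
        # use the undistorted normalized ray; rows from M = [R | t]
        xn = cam.pixel_to_normalized(px)
        M = np.hstack([cam.R, cam.t[:, None]])
        rows.append(conf * (xn[0] * M[2] - M[0]))
        rows.append(conf * (xn[1] * M[2] - M[1]))
    A = np.asarray(rows)
    _, s, vt = np.linalg.svd(A, full_matrices=False)
    if s[2] < 1e-10 * s[0]:
        return nan3, float("nan"), False        # degenerate geometry
    Xh = vt[-1]
    if abs(Xh[3]) < 1e-12 * np.linalg.norm(Xh[:3]):
        return nan3, float("nan"), False        # point at infinity
    X = Xh[:3] / Xh[3]
    sq = 0.0
    for cam, px, _ in used:
        try:
            pred = cam.project(X)
        except ValueError:
            return nan3, float("nan"), False    # behind a camera: reject
        sq += float(np.sum((pred - px) ** 2))
    rms = float(np.sqrt(sq / len(used)))
    return X, rms, True


def triangulate_poses(
    cameras: Sequence[CameraModel],
    sequences: Sequence[Sequence[Pose2D]],
    min_views: int = 2,
    fps: float = 30.0,
    frame_offsets: Optional[Sequence[int]] = None,
) -> list[Pose3D]:
    """Triangulate per-camera 2D sequences into 3D poses.

    Frames are matched by index; ``frame_offsets`` applies a constant
    per-camera shift (frames) before matching, for coarse synchronisation.
    """
    if len(cameras) != len(sequences):
        raise ValueError("one 2D sequence per camera is required")
    offs = list(frame_offsets) if frame_offsets is not None else [0] * len(cameras)
    maps = []
    for seq, off in zip(sequences, offs):
        maps.append({p.frame_index + off: p for p in seq})
    indices = sorted(set().union(*[m.keys() for m in maps])) if maps else []
    out: list[Pose3D] = []
    for idx in indices:
        xyz = np.full((keypoints.N_KEYPOINTS, 3), np.nan)
        valid = np.zeros(keypoints.N_KEYPOINTS, dtype=bool)
        rms = np.full(keypoints.N_KEYPOINTS, np.nan)
        for k in range(keypoints.N_KEYPOINTS):
            obs = []
            for cam, m in zip(cameras, maps):
                p = m.get(idx)
                if p is None:
                    continue
                x, y, c = p.keypoints[k]
                if c > 0:
                    obs.append((cam, (x, y), c))
            X, r, ok = triangulate(obs, min_views=min_views)
            if ok:
                xyz[k] = X
                rms[k] = r
                valid[k] = True
        out.append(Pose3D(idx, idx / fps, xyz, valid, rms))
    return out


# -- PCK ------------------------------------------------------------------

def _torso_diagonal(kp: np.ndarray) -> float:
    pairs = (
        (keypoints.L_SHOULDER, keypoints.R_HIP),
        (keypoints.R_SHOULDER, keypoints.L_HIP),
        (keypoints.NECK, keypoints.MID_HIP),
    )
    for a, b in pairs:
        if kp[a, 2] > 0 and kp[b, 2] > 0:
            d = float(np.hypot(*(kp[a, :2] - kp[b, :2])))
            if d > 0:
                return d
    raise ValueError("annotation lacks the torso keypoints needed for the PCK reference")


def pck(
    predicted: Pose2D | Sequence[Pose2D],
    annotated: Pose2D | Sequence[Pose2D],
    alpha: float = 0.2,
    reference: str = "torso_diagonal",
    reference_px: Optional[float] = None,
) -> float:
    """Percentage of correct keypoints.

    A predicted keypoint is correct when it lies within ``alpha`` times the
    reference distance of its annotation.  The evaluated set is the
    annotated (confidence > 0) keypoints; an annotated keypoint the
    predictor missed counts as incorrect.  ``reference`` is the annotated
    torso diagonal per frame, or a fixed pixel distance (``fixed_px`` with
    ``reference_px``).
    """
    preds = [predicted] if isinstance(predicted, Pose2D) else list(predicted)
    annos = [annotated] if isinstance(annotated, Pose2D) else list(annotated)
    if len(preds) != len(annos):
        raise ValueError("predicted and annotated frame counts differ")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    n_eval = 0
    n_ok = 0
    for p, a in zip(preds, annos):
        mask = a.keypoints[:, 2] > 0
        if not np.any(mask):
            continue
        if reference == "torso_diagonal":
            ref = _torso_diagonal(a.keypoints)
        elif reference == "fixed_px":
            if reference_px is None or reference_px <= 0:
                raise ValueError("fixed_px reference requires a positive reference_px")
            ref = float(reference_px)
        else:
            raise ValueError(f"unknown PCK reference {reference!r}")
        thr = alpha * ref
        d = np.hypot(
            p.keypoints[:, 0] - a.keypoints[:, 0],
            p.keypoints[:, 1] - a.keypoints[:, 1],
        )
        ok = (p.keypoints[:, 2] > 0) & (d <= thr)
        n_eval += int(np.count_nonzero(mask))
        n_ok += int(np.count_nonzero(ok & mask))
    if n_eval == 0:
        raise ValueError("no evaluable keypoints")
    return 100.0 * n_ok / n_eval
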