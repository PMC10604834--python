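"""Body-segment parameters and segment-level CoM geometry.

Whole-body centre of mass is estimated with the segmental method: each
modeled segment (i, j) contributes mass m_ij at the point

    C_ij = P_i + k_ij (P_j - P_i),

where P_i is the proximal joint, P_j the distal joint and k_ij the
dimensionless proximal CoM coefficient.  The default sex-specific table
(mass fractions from the Plagenhoef 1983 water-immersion statistics, k
values for forearm / upper arm / trunk of 0.430/0.436/0.630 for males and
0.434/0.458/0.569 for females) ships with the package as plain YAML and
can be overridden with any table of the same shape.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import keypoints

SEXES = ("male", "female")


@dataclass(frozen=True)
class SegmentParams:
    """One body segment: joint pair, mass fraction and proximal CoM coefficient."""

    name: str
    proximal_joint: int
    distal_joint: int
    mass_fraction: float
    k: float
    side: str = "C"

    def __post_init__(self) -> None:
        n = keypoints.N_KEYPOINTS
        if not (0 <= self.proximal_joint < n and 0 <= self.distal_joint < n):
            raise ValueError(
                f"segment {self.name!r}: joint indices must be in [0, {n})"
            )
        if self.proximal_joint == self.distal_joint:
            raise ValueError(f"segment {self.name!r}: proximal == distal joint")
        if not 0.0 < self.mass_fraction < 1.0:
            raise ValueError(f"segment {self.name!r}: mass_fraction must be in (0, 1)")
        if not 0.0 <= self.k <= 1.0:
            raise ValueError(f"segment {self.name!r}: k must be in [0, 1]")

    @property
    def label(self) -> str:
        return self.name if self.side == "C" else f"{self.name}_{self.side}"


@dataclass
class BodyModel:
    """A participant-level segmental model.

    ``total_mass`` is the whole-body mass M in kg.  The CoM location is
    invariant to M (fractions normalise out), so a template with
    ``total_mass=1`` is a valid model for geometry-only work.
    ``segment_volumes`` (dm^3, keyed by segment label) are carried for the
    hypogravity ballast design and are optional.
    """

    sex: str
    total_mass: float
    segments: tuple[SegmentParams, ...]
    segment_volumes: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex label {self.sex!r}; expected one of {SEXES}")
        if not self.total_mass > 0:
            raise ValueError("total_mass must be > 0")
        self.segments = tuple(self.segments)
        frac = sum(s.mass_fraction for s in self.segments)
        if not 0.0 < frac <= 1.0:
            raise ValueError(
                f"segment mass fractions sum to {frac:.4f}; must be in (0, 1]"
            )

    @property
    def modeled_mass(self) -> float:
        """M of the segmental sum: total mass of all modeled segments (kg)."""
        return self.total_mass * sum(s.mass_fraction for s in self.segments)

    def segment_mass(self, seg: SegmentParams) -> float:
        return self.total_mass * seg.mass_fraction

    def required_keypoints(self) -> frozenset[int]:
        out: set[int] = set()
        for s in self.segments:
            out.add(s.proximal_joint)
            out.add(s.distal_joint)
        return frozenset(out)


def _default_table_path() -> Path:
    return Path(str(resources.files("lunarcom").joinpath("data/segment_table.yaml")))


@lru_cache(maxsize=4)
def _load_table(path_str: str) -> tuple[dict, ...]:
    with open(path_str, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return tuple(raw["segments"])


def default_segment_table(
    sex: str,
    total_mass: float = 1.0,
    table_path: Optional[str | Path] = None,
) -> BodyModel:
    """Build the default sex-specific :class:`BodyModel`.

    Parameters
    ----------
    sex : {"male", "female"}
    total_mass : whole-body mass in kg (defaults to 1, a geometry template).
    table_path : optional override YAML with the same columns as the shipped
        ``data/segment_table.yaml``.

    The function is pure: repeated calls return equal, independent objects.
    """
    if sex not in SEXES:
        raise ValueError(f"unknown sex label {sex!r}; expected one of {SEXES}")
    path = Path(table_path) if table_path is not None else _default_table_path()
    rows = _load_table(str(path))
    segs = []
    for row in copy.deepcopy(rows):
        segs.append(
            SegmentParams(
                name=row["name"],
                side=row.get("side", "C"),
                proximal_joint=int(row["proximal_idx"]),
                distal_joint=int(row["distal_idx"]),
                mass_fraction=float(row[f"mass_fraction_{sex}"]),
                k=float(row[f"k_{sex}"]),
            )
        )
    return BodyModel(sex=sex, total_mass=total_mass, segments=tuple(segs))


def segment_com(p_prox, p_dist, k: float) -> np.ndarray:
    """CoM of one segment: ``p_prox + k * (p_dist - p_prox)``.

    ``k`` is measured from the proximal end; ``k=0`` returns the proximal
    joint, ``k=1`` the distal joint.  Inputs are 3-vectors (cm); the result
    is affine-equivariant and lies on the segment for k in [0, 1].
    """
    p = np.asarray(p_prox, dtype=float)
    q = np.asarray(p_dist, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q)) and np.isfinite(k)):
        raise ValueError("segment_com requires finite inputs")
    if not 0.0 <= k <= 1.0:
        raise ValueError(f"k must be in [0, 1], got {k}")
    return p + k * (q - p)
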