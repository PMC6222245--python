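"""Core geometric types: points, trajectories, plans, affine transforms.

All world coordinates are RAS millimetres; voxel indices are 0-based.  A
trajectory is the straight segment from an entry point (EP) on the head
surface to a deep target point (TP), and every trajectory carries a `space`
tag (``"subject"`` or ``"average"``) that is propagated through transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .errors import AffineFormatError, ContractError

SUBJECT = "subject"
AVERAGE = "average"
_SPACES = (SUBJECT, AVERAGE)


@dataclass(frozen=True)
class Point3:
    """A point in world coordinates (RAS, mm)."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.x, self.y, self.z])):
            raise ContractError(f"non-finite coordinate in {self!r}")

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @staticmethod
    def from_array(a: Iterable[float]) -> "Point3":
        x, y, z = (float(v) for v in a)
        return Point3(x, y, z)

    def distance_to(self, other: "Point3") -> float:
        return float(np.linalg.norm(self.to_array() - other.to_array()))


@dataclass(frozen=True)
class Trajectory:
    """A single electrode trajectory, from entry point to target point."""

    plan_id: str
    electrode_id: str
    entry: Point3
    target: Point3
    space: str = SUBJECT

    def __post_init__(self) -> None:
        if self.space not in _SPACES:
            raise ContractError(f"unknown space tag {self.space!r}")
        if self.length == 0.0:
            raise ContractError(
                f"zero-length trajectory {self.plan_id}/{self.electrode_id}: "
                f"entry equals target"
            )

    @property
    def length(self) -> float:
        return self.entry.distance_to(self.target)

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from entry towards target."""
        d = self.target.to_array() - self.entry.to_array()
        return d / np.linalg.norm(d)


@dataclass
class Plan:
    """An implantation plan: the ordered set of trajectories of one patient."""

    plan_id: str
    patient_id: str
    trajectories: list[Trajectory] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.trajectories) == 0:
            raise ContractError(f"plan {self.plan_id} has no trajectories")
        seen: set[str] = set()
        for tr in self.trajectories:
            if tr.electrode_id in seen:
                raise ContractError(
                    f"duplicate electrode_id {tr.electrode_id!r} in plan {self.plan_id}"
                )
            seen.add(tr.electrode_id)
        spaces = {tr.space for tr in self.trajectories}
        if len(spaces) > 1:
            raise ContractError(f"plan {self.plan_id} mixes spaces {spaces}")

    @property
    def space(self) -> str:
        return self.trajectories[0].space

    @property
    def n_electrodes(self) -> int:
        return len(self.trajectories)


class AffineTransform:
    """A 4x4 homogeneous affine mapping RAS mm coordinates between spaces.

    By convention a registration affine maps subject space to the common
    average space; ``inverse()`` gives the average-to-subject map used when
    initialising a plan for a new patient.
    """

    def __init__(self, matrix: np.ndarray):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise AffineFormatError(f"affine must be 4x4, got shape {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise AffineFormatError(f"last affine row must be (0,0,0,1), got {m[3]}")
        if abs(np.linalg.det(m[:3, :3])) <= 1e-12:
            raise AffineFormatError("affine is singular (|det| <= 1e-12)")
        self.matrix = m

    def apply(self, point: Point3) -> Point3:
        v = self.matrix @ np.append(point.to_array(), 1.0)
        return Point3.from_array(v[:3])

    def apply_array(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array of points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: (self @ other)(p) = self(other(p))."""
        return AffineTransform(self.matrix @ other.matrix)

    @staticmethod
    def identity() -> "AffineTransform":
        return AffineTransform(np.eye(4))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AffineTransform) and np.array_equal(
            self.matrix, other.matrix
        )

    def __repr__(self) -> str:
        return f"AffineTransform({self.matrix!r})"


def transform_trajectory(tr: Trajectory, t: AffineTransform, new_space: str) -> Trajectory:
    """Map a trajectory's endpoints through an affine and retag its space."""
    return replace(
        tr,
        entry=t.apply(tr.entry),
        target=t.apply(tr.target),
        space=new_space,
    )
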