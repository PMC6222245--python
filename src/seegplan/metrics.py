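"""Quantitative safety indices for trajectories.

Two indices are computed, the same ones used to compare manual and
initialised plans: the insertion angle at the entry point (deviation of the
electrode direction from the local surface normal; 0 deg = perpendicular
insertion, the ideal) and the minimum distance from vessels, assessed
separately over the proximal (first) and distal (second) tract of the
trajectory.  No trajectory optimisation is performed here — these are
read-only scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ContractError
from .geometry import AffineTransform, Point3, Trajectory

logger = logging.getLogger(__name__)

DEFAULT_SPLIT_DEPTH_MM = 10.0


@dataclass
class VesselMask:
    """Binary vessel segmentation with its voxel-to-world affine."""

    mask: np.ndarray
    vox2world: AffineTransform

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ContractError("vessel mask must be 3-D")

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Physical voxel edge lengths (mm) from the affine's column norms."""
        return np.linalg.norm(self.vox2world.matrix[:3, :3], axis=0)


@dataclass
class RiskMetrics:
    insertion_angle_deg: float
    min_vessel_dist_tract1_mm: float
    min_vessel_dist_tract2_mm: float


def insertion_angle(tr: Trajectory, surface_point: Point3,
                    surface_normal: np.ndarray) -> float:
    """Angle (degrees) between the trajectory direction and the surface normal.

    0 deg means the electrode enters perpendicular to the surface (ideal);
    90 deg means it grazes the surface.  ``surface_point`` documents where
    the normal was taken and is not used in the formula.
    """
    n = np.asarray(surface_normal, dtype=float)
    norm = np.linalg.norm(n)
    if not np.isclose(norm, 1.0, atol=1e-6):
        raise ContractError(f"surface normal must be unit length, |n|={norm:.6g}")
    cos = abs(float(np.dot(tr.direction, n)))
    return float(np.degrees(np.arccos(np.clip(cos, 0.0, 1.0))))


def vessel_distance(
    tr: Trajectory,
    vessels: VesselMask,
    split_depth: float = DEFAULT_SPLIT_DEPTH_MM,
    step: float = 1.0,
) -> tuple[float, float]:
    """Minimum distance (mm) from vessels in the first and second tract.

    The Euclidean distance transform of the vessel mask is sampled along the
    trajectory at ``step`` mm intervals (plus the end-point); tract 1 is the
    samples with arc-length <= ``split_depth`` from the entry, tract 2 the
    rest.  An empty mask yields (+inf, +inf) with a warning.  Distances are
    voxel-centre based, accurate to about one voxel diagonal.
    """
    if step <= 0:
        raise ContractError("step must be positive")
    if not (0.0 < split_depth < tr.length):
        raise ContractError(
            f"split_depth must lie strictly inside (0, {tr.length:.3f}), got {split_depth}"
        )
    if not vessels.mask.any():
        logger.warning("empty vessel mask: vessel distances are +inf")
        return (np.inf, np.inf)

    edt = ndimage.distance_transform_edt(~vessels.mask, sampling=vessels.voxel_sizes)

    arcs = np.arange(0.0, tr.length, step)
    if len(arcs) == 0 or arcs[-1] < tr.length:
        arcs = np.append(arcs, tr.length)
    points = tr.entry.to_array()[None, :] + arcs[:, None] * tr.direction[None, :]
    vox = np.rint(vessels.vox2world.inverse().apply_array(points)).astype(int)
    vox = np.clip(vox, 0, np.array(vessels.mask.shape) - 1)  # clamp outside samples
    dists = edt[vox[:, 0], vox[:, 1], vox[:, 2]]

    tract1 = dists[arcs <= split_depth]
    tract2 = dists[arcs > split_depth]
    d1 = float(tract1.min()) if len(tract1) else np.inf
    d2 = float(tract2.min()) if len(tract2) else np.inf
    return (d1, d2)


def risk_metrics(
    tr: Trajectory,
    vessels: VesselMask,
    surface_point: Point3,
    surface_normal: np.ndarray,
    split_depth: float = DEFAULT_SPLIT_DEPTH_MM,
    step: float = 1.0,
) -> RiskMetrics:
    d1, d2 = vessel_distance(tr, vessels, split_depth=split_depth, step=step)
    return RiskMetrics(
        insertion_angle_deg=insertion_angle(tr, surface_point, surface_normal),
        min_vessel_dist_tract1_mm=d1,
        min_vessel_dist_tract2_mm=d2,
    )
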