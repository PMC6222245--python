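"""Exploratory patterns and mean trajectories.

Trajectories from all patients that share a descriptor form an exploratory
pattern.  Each pattern is compressed, in the common average space, into a
small set of mean trajectories by k-means on the joint 6-D (entry, target)
coordinates.  The initial cluster count is U, the maximum number of
same-descriptor electrodes any single plan uses, because a plan that places
several electrodes in one pattern does so to cover distinct sub-regions.
A cluster is significant only if it holds at least a fraction (default 5%)
of the pattern's trajectories; otherwise k is decremented and k-means rerun,
down to the k = 1 floor.  Each surviving cluster becomes a mean trajectory:
centroid entry/target plus scalar RMS dispersions.

Clustering is joint over the 6-D vector (entry ⊕ target) so the entry-target
pairing of each cluster is preserved; clustering entries and targets
separately could pair entries with the wrong targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .descriptor import Descriptor
from .errors import ContractError, SpaceMismatchError
from .geometry import AVERAGE, AffineTransform, Plan, Point3, Trajectory, transform_trajectory
from .model import MeanTrajectory

logger = logging.getLogger(__name__)

#: k-means restarts per k; k-means++ initialisation, seeded, for reproducibility
KMEANS_N_INIT = 10


@dataclass
class ExploratoryPattern:
    """All trajectories (across patients) sharing one descriptor."""

    descriptor: Descriptor
    members: list[Trajectory] = field(default_factory=list)

    def __post_init__(self) -> None:
        for tr in self.members:
            if tr.space != AVERAGE:
                raise SpaceMismatchError(
                    f"pattern member {tr.plan_id}/{tr.electrode_id} is in "
                    f"{tr.space!r} space; patterns live in the average space"
                )

    @property
    def size(self) -> int:
        return len(self.members)

    def coordinates(self) -> np.ndarray:
        """(n, 6) array of entry ⊕ target coordinates."""
        return np.array(
            [np.concatenate([tr.entry.to_array(), tr.target.to_array()])
             for tr in self.members]
        )


def to_average_space(plan: Plan, t: AffineTransform) -> Plan:
    """Map a subject-space plan into the average space through t."""
    if plan.space != "subject":
        raise ContractError(f"plan {plan.plan_id} is already in {plan.space!r} space")
    return Plan(
        plan_id=plan.plan_id,
        patient_id=plan.patient_id,
        trajectories=[transform_trajectory(tr, t, AVERAGE) for tr in plan.trajectories],
    )


def group_patterns(
    plans: list[Plan],
    descriptors: dict[tuple[str, str], Descriptor | None],
) -> list[ExploratoryPattern]:
    """Partition non-outlier trajectories by exact descriptor equality.

    ``descriptors`` maps (plan_id, electrode_id) to the trajectory's
    descriptor, or None for outliers (which never enter a pattern).
    Patterns are sorted by (entry_zone, target_zone) for determinism.
    """
    buckets: dict[Descriptor, list[Trajectory]] = {}
    for plan in plans:
        for tr in plan.trajectories:
            if tr.space != AVERAGE:
                raise SpaceMismatchError(
                    f"trajectory {tr.plan_id}/{tr.electrode_id} is in {tr.space!r} "
                    f"space; transform plans to the average space first"
                )
            d = descriptors.get((tr.plan_id, tr.electrode_id))
            if d is None:
                continue
            buckets.setdefault(d, []).append(tr)
    return [
        ExploratoryPattern(descriptor=d, members=buckets[d])
        for d in sorted(buckets)
    ]


def compute_U(pattern: ExploratoryPattern) -> int:
    """Maximum number of same-pattern electrodes used by any single plan."""
    if pattern.size == 0:
        raise ContractError("empty pattern")
    counts: dict[str, int] = {}
    for tr in pattern.members:
        counts[tr.plan_id] = counts.get(tr.plan_id, 0) + 1
    return max(counts.values())


def _cluster_once(coords: np.ndarray, k: int, seed: int) -> np.ndarray:
    """One k-means run at fixed k; returns integer labels per member."""
    if k == 1:
        return np.zeros(len(coords), dtype=int)
    km = KMeans(n_clusters=k, n_init=KMEANS_N_INIT, random_state=seed)
    return km.fit_predict(coords)


def _clusters_significant(labels: np.ndarray, k: int, min_frac: float) -> bool:
    n = len(labels)
    sizes = np.bincount(labels, minlength=k)
    # ">= 5%" on the real-valued product, no rounding before comparison
    return bool(np.all(sizes >= min_frac * n))


def build_mean_trajectories(
    pattern: ExploratoryPattern,
    U_init: int,
    min_frac: float = 0.05,
    seed: int = 0,
) -> list[MeanTrajectory]:
    """Compress a pattern into mean trajectories by iterative k-means.

    Starts at k = U_init; whenever any cluster holds fewer than
    ``min_frac`` of the pattern's members, k is decremented and k-means
    rerun, until all clusters are significant or k reaches 1.  Mean
    trajectory indices u are assigned by descending member count, ties
    broken by entry-point lexicographic order.
    """
    if U_init < 1:
        raise ContractError(f"U_init must be >= 1, got {U_init}")
    if pattern.size == 0:
        raise ContractError("empty pattern")
    coords = pattern.coordinates()
    k = U_init
    if k > pattern.size:
        logger.warning(
            "pattern %s: U_init=%d exceeds pattern size %d; clamping",
            pattern.descriptor, U_init, pattern.size,
        )
        k = pattern.size
    while True:
        labels = _cluster_once(coords, k, seed)
        if k == 1 or _clusters_significant(labels, k, min_frac):
            break
        k -= 1

    clusters = []
    for c in range(k):
        mask = labels == c
        members = [tr for tr, m in zip(pattern.members, mask) if m]
        pts = coords[mask]
        mean6 = pts.mean(axis=0)
        mean_entry, mean_target = mean6[:3], mean6[3:]
        sigma_entry = float(np.sqrt(np.mean(np.sum((pts[:, :3] - mean_entry) ** 2, axis=1))))
        sigma_target = float(np.sqrt(np.mean(np.sum((pts[:, 3:] - mean_target) ** 2, axis=1))))
        clusters.append((members, mean_entry, mean_target, sigma_entry, sigma_target))

    # deterministic u ordering: descending size, ties by entry lexicographic
    clusters.sort(key=lambda c: (-len(c[0]), tuple(c[1])))
    out = []
    for u, (members, mean_entry, mean_target, s_ep, s_tp) in enumerate(clusters, start=1):
        out.append(MeanTrajectory(
            descriptor=pattern.descriptor,
            index_u=u,
            mean_entry=Point3.from_array(mean_entry),
            mean_target=Point3.from_array(mean_target),
            sigma_entry=s_ep,
            sigma_target=s_tp,
            n_members=len(members),
            member_refs=[(tr.plan_id, tr.electrode_id) for tr in members],
        ))
    return out
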