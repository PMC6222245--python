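"""Planning strategies: clustering plans by the mean trajectories they use.

Each plan is encoded as a fixed-length boolean vector over the model's
ordered mean-trajectory list (bit y set iff the plan contributed at least
one trajectory to mean trajectory y).  Plans can be hierarchically related
(one plan may be the composition of others), so plans are clustered
agglomeratively on the pairwise Jaccard distance of these vectors, and flat
groups are read off the dendrogram at a cut threshold.  Each group yields a
strategy: bit y is kept only when at least two member plans support it,
which filters patient-specific electrodes out of the reusable strategy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ContractError
from .model import ModelBundle, Strategy

logger = logging.getLogger(__name__)

DEFAULT_LINKAGE = "average"
DEFAULT_CUT = 0.7


@dataclass
class PlanVector:
    """Boolean presence vector of one plan over the ordered mT list."""

    plan_id: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)


def plans_to_vectors(bundle: ModelBundle, plan_ids: list[str] | None = None) -> list[PlanVector]:
    """Build one presence vector per plan from the mTs' member references.

    Membership comes from the clustering assignment recorded in each mean
    trajectory's ``member_refs``, not from re-matching coordinates.  When
    ``plan_ids`` is given, vectors are emitted for exactly those plans (a
    plan with no non-outlier trajectory gets an all-False vector with a
    logged warning); otherwise every plan referenced by some mT gets one.
    """
    n = len(bundle.mean_trajectories)
    membership: dict[str, set[int]] = {}
    for y, mt in enumerate(bundle.mean_trajectories):
        for plan_id, _electrode_id in mt.member_refs:
            membership.setdefault(plan_id, set()).add(y)
    if plan_ids is None:
        plan_ids = sorted(membership)
    out = []
    for pid in plan_ids:
        bits = np.zeros(n, dtype=bool)
        for y in membership.get(pid, ()):
            bits[y] = True
        if not bits.any():
            logger.warning("plan %r contributed no non-outlier trajectory; all-False vector", pid)
        out.append(PlanVector(plan_id=pid, bits=bits))
    return out


def jaccard_distance(f1: np.ndarray, f2: np.ndarray) -> float:
    """Jaccard distance 1 - |f1 ∧ f2| / |f1 ∨ f2| between boolean vectors.

    Two all-False vectors are at distance 0 by convention.
    """
    a = np.asarray(f1, dtype=bool)
    b = np.asarray(f2, dtype=bool)
    if a.shape != b.shape:
        raise ContractError(f"vector length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return 1.0 - np.count_nonzero(a & b) / union


def jaccard_matrix(vectors: list[PlanVector]) -> np.ndarray:
    """Square pairwise Jaccard distance matrix."""
    n = len(vectors)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jaccard_distance(vectors[i].bits, vectors[j].bits)
    return d


def cluster_plans(
    vectors: list[PlanVector],
    cut_threshold: float = DEFAULT_CUT,
    linkage: str = DEFAULT_LINKAGE,
) -> list[list[str]]:
    """Agglomerative clustering of plan vectors; flat groups at a dendrogram cut.

    Returns plan-id groups ordered by descending size (ties by first plan id).
    Two plans end up in the same group iff their cophenetic distance is
    <= ``cut_threshold``.
    """
    if len(vectors) < 2:
        raise ContractError("need at least 2 plan vectors to cluster")
    dist = jaccard_matrix(vectors)
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    flat = hierarchy.fcluster(z, t=cut_threshold, criterion="distance")
    groups: dict[int, list[str]] = {}
    for label, vec in zip(flat, vectors):
        groups.setdefault(int(label), []).append(vec.plan_id)
    return sorted(groups.values(), key=lambda g: (-len(g), g[0]))


def linkage_matrix(vectors: list[PlanVector], linkage: str = DEFAULT_LINKAGE) -> np.ndarray:
    """Scipy linkage matrix for dendrogram export / QA plots."""
    dist = jaccard_matrix(vectors)
    return hierarchy.linkage(squareform(dist, checks=False), method=linkage)


def derive_strategy(group: list[PlanVector], strategy_id: str, name: str | None = None) -> Strategy:
    """Reduce a group of plan vectors to its strategy bit-vector.

    Bit y is True iff at least 2 member plans have bit y set.  A singleton
    group necessarily yields an all-False (degenerate) strategy; it is kept,
    flagged in the log, to preserve the G-group partition.
    """
    if len(group) == 0:
        raise ContractError("empty plan group")
    stacked = np.stack([v.bits for v in group])
    support = stacked.sum(axis=0)
    bits = support >= 2
    if not bits.any():
        logger.warning("strategy %r is degenerate (all-False bit-vector)", strategy_id)
    return Strategy(
        strategy_id=strategy_id,
        bits=[bool(b) for b in bits],
        member_plan_ids=[v.plan_id for v in group],
        name=name,
    )


def derive_strategies(
    bundle: ModelBundle,
    cut_threshold: float = DEFAULT_CUT,
    linkage: str = DEFAULT_LINKAGE,
) -> list[Strategy]:
    """Full strategy stage: vectors -> clustering -> one strategy per group."""
    vectors = plans_to_vectors(bundle)
    by_id = {v.plan_id: v for v in vectors}
    groups = cluster_plans(vectors, cut_threshold=cut_threshold, linkage=linkage)
    return [
        derive_strategy([by_id[pid] for pid in group], strategy_id=f"S{g + 1}")
        for g, group in enumerate(groups)
    ]
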