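"""End-to-end orchestration of the model-building stages.

This is thin glue over the stage modules: normalise plans to the average
space, classify every trajectory, mine exploratory patterns into mean
trajectories, and (separately) derive planning strategies.  The heavy
lifting lives in :mod:`descriptor`, :mod:`patterns` and :mod:`strategies`.
"""

from __future__ import annotations

import logging

from .atlas import LabelVolume
from .descriptor import Descriptor, ZoneConfig, describe_trajectory
from .errors import ContractError
from .geometry import AVERAGE, AffineTransform, Plan
from .model import ModelBundle
from .patterns import build_mean_trajectories, compute_U, group_patterns, to_average_space
from .strategies import DEFAULT_CUT, DEFAULT_LINKAGE, derive_strategies

logger = logging.getLogger(__name__)


def describe_plans(
    plans: list[Plan],
    atlas: LabelVolume,
    zone_config: ZoneConfig,
    step: float = 1.0,
) -> dict[tuple[str, str], Descriptor | None]:
    """Descriptor (or None for outliers) per (plan_id, electrode_id)."""
    out: dict[tuple[str, str], Descriptor | None] = {}
    for plan in plans:
        for tr in plan.trajectories:
            out[(tr.plan_id, tr.electrode_id)] = describe_trajectory(
                tr, atlas, zone_config, step=step, space=AVERAGE
            )
    return out


def build_model_bundle(
    plans: list[Plan],
    affines: dict[str, AffineTransform],
    atlas: LabelVolume,
    zone_config: ZoneConfig,
    step: float = 1.0,
    min_frac: float = 0.05,
    seed: int = 0,
    provenance: dict | None = None,
) -> ModelBundle:
    """Mine a cohort of subject-space plans into a model bundle (no strategies).

    ``affines`` maps patient_id to the subject->average registration; the
    atlas must live in the average space.  The bundle's mean-trajectory
    order is patterns sorted by (entry_zone, target_zone), then by index u
    within each pattern — deterministic given the seed.
    """
    missing = [p.patient_id for p in plans if p.patient_id not in affines]
    if missing:
        raise ContractError(f"no registration affine for patient(s) {missing}")
    avg_plans = [to_average_space(p, affines[p.patient_id]) for p in plans]
    descriptors = describe_plans(avg_plans, atlas, zone_config, step=step)
    n_outliers = sum(1 for d in descriptors.values() if d is None)
    if n_outliers:
        logger.info("%d trajectories classified as outliers", n_outliers)

    mean_trajectories = []
    for pattern in group_patterns(avg_plans, descriptors):
        u = compute_U(pattern)
        mean_trajectories.extend(
            build_mean_trajectories(pattern, U_init=u, min_frac=min_frac, seed=seed)
        )

    prov = {
        "n_patients": len({p.patient_id for p in plans}),
        "n_plans": len(plans),
        "n_trajectories": sum(p.n_electrodes for p in plans),
        "n_outliers": n_outliers,
        "step_mm": step,
        "min_frac": min_frac,
        "seed": seed,
    }
    if provenance:
        prov.update(provenance)
    return ModelBundle(
        mean_trajectories=mean_trajectories,
        strategies=[],
        zone_config=zone_config,
        provenance=prov,
    )


def add_strategies(
    bundle: ModelBundle,
    cut_threshold: float = DEFAULT_CUT,
    linkage: str = DEFAULT_LINKAGE,
) -> ModelBundle:
    """Derive planning strategies and attach them to the bundle in place."""
    bundle.strategies = derive_strategies(
        bundle, cut_threshold=cut_threshold, linkage=linkage
    )
    bundle.provenance["cut_threshold"] = cut_threshold
    bundle.provenance["linkage"] = linkage
    bundle.validate()
    return bundle
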