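"""Plan initialisation for a new subject and its validation.

A selected strategy's mean trajectories are mapped from the average space
into the subject space through the inverse of the subject's registration
affine, producing an initialised plan (IP).  Validation against a manual
plan (MP) pairs initialised and manual trajectories one-to-one by
minimum-cost linear assignment on the summed entry- and target-point
distances (optionally constrained to pairs sharing a descriptor) and applies
the 2-sigma criterion: a trajectory is correctly mapped when its entry-point
distance is <= 2*sigma of the mean trajectory's entry dispersion AND its
target-point distance is <= 2*sigma of the target dispersion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .descriptor import Descriptor
from .errors import ContractError
from .geometry import SUBJECT, AffineTransform, Plan, Trajectory, transform_trajectory
from .model import ModelBundle, MeanTrajectory

logger = logging.getLogger(__name__)

_FORBIDDEN = 1e12  # assignment cost for descriptor-incompatible pairs


@dataclass
class InitializedPlan:
    """A strategy mapped into a subject's space: (mT index y, trajectory) pairs."""

    patient_id: str
    entries: list[tuple[int, Trajectory]] = field(default_factory=list)  # y is 1-based

    def __post_init__(self) -> None:
        ys = [y for y, _ in self.entries]
        if len(ys) != len(set(ys)):
            raise ContractError("duplicate mT indices in initialised plan")
        for _, tr in self.entries:
            if tr.space != SUBJECT:
                raise ContractError("initialised trajectories must be in subject space")


@dataclass
class PairedTrajectories:
    """One-to-one pairing between an initialised plan and a manual plan."""

    pairs: list[tuple[int, str, Trajectory, Trajectory]]  # (y, manual id, IP tr, MP tr)
    unpaired_initialized: list[int] = field(default_factory=list)  # mT indices y
    unpaired_manual: list[str] = field(default_factory=list)  # electrode ids


@dataclass
class PairResult:
    mt_index: int
    manual_electrode_id: str
    d_ep: float
    d_tp: float
    sigma_ep: float
    sigma_tp: float
    passed: bool
    degenerate_sigma: bool = False  # singleton mT (sigma = 0): only an exact hit passes


@dataclass
class ValidationReport:
    pairs: list[PairResult]
    fraction_mapped: float
    unpaired_manual: list[str] = field(default_factory=list)
    unpaired_initialized: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pairs": [vars(p).copy() for p in self.pairs],
            "fraction_mapped": self.fraction_mapped,
            "unpaired_manual": list(self.unpaired_manual),
            "unpaired_initialized": list(self.unpaired_initialized),
        }


def init_plan(
    bundle: ModelBundle,
    strategy_id: str,
    subject_affine: AffineTransform,
    patient_id: str = "new_subject",
) -> InitializedPlan:
    """Map a strategy's mean trajectories into the subject space.

    ``subject_affine`` maps subject -> average; its inverse carries each
    selected mean trajectory into the subject.  Electrode ids are generated
    as ``mT<y>`` from the 1-based mT index.
    """
    strategy = bundle.strategy_by_id(strategy_id)
    inv = subject_affine.inverse()
    entries = []
    for y0, (bit, mt) in enumerate(zip(strategy.bits, bundle.mean_trajectories)):
        if not bit:
            continue
        y = y0 + 1
        tr = Trajectory(
            plan_id=f"IP_{patient_id}",
            electrode_id=f"mT{y}",
            entry=inv.apply(mt.mean_entry),
            target=inv.apply(mt.mean_target),
            space=SUBJECT,
        )
        entries.append((y, tr))
    if not entries:
        logger.warning("strategy %r is all-False: empty initialised plan", strategy_id)
    return InitializedPlan(patient_id=patient_id, entries=entries)


def _pair_cost(ip_tr: Trajectory, mp_tr: Trajectory) -> float:
    return ip_tr.entry.distance_to(mp_tr.entry) + ip_tr.target.distance_to(mp_tr.target)


def match_trajectories(
    ip: InitializedPlan,
    manual: Plan,
    bundle: ModelBundle,
    manual_descriptors: dict[str, Descriptor | None] | None = None,
) -> PairedTrajectories:
    """One-to-one IP/MP pairing minimising total entry + target distance.

    Solved as a rectangular linear assignment.  When a manual trajectory's
    descriptor is computable (given via ``manual_descriptors``, keyed by
    electrode id), only pairs sharing the mean trajectory's descriptor are
    admissible.  Surplus trajectories on either side are reported unpaired.
    """
    if manual.space != SUBJECT:
        raise ContractError("manual plan must be in subject space")
    if not ip.entries:
        return PairedTrajectories(
            pairs=[],
            unpaired_manual=[tr.electrode_id for tr in manual.trajectories],
        )
    mts = bundle.mean_trajectories
    cost = np.zeros((len(ip.entries), len(manual.trajectories)))
    for i, (y, ip_tr) in enumerate(ip.entries):
        mt_desc = mts[y - 1].descriptor
        for j, mp_tr in enumerate(manual.trajectories):
            c = _pair_cost(ip_tr, mp_tr)
            if manual_descriptors is not None:
                mp_desc = manual_descriptors.get(mp_tr.electrode_id)
                if mp_desc is not None and mp_desc != mt_desc:
                    c = _FORBIDDEN
            cost[i, j] = c
    rows, cols = linear_sum_assignment(cost)
    pairs = []
    used_rows, used_cols = set(), set()
    for i, j in zip(rows, cols):
        if cost[i, j] >= _FORBIDDEN:
            continue  # descriptor-incompatible; leave both unpaired
        y, ip_tr = ip.entries[i]
        mp_tr = manual.trajectories[j]
        pairs.append((y, mp_tr.electrode_id, ip_tr, mp_tr))
        used_rows.add(i)
        used_cols.add(j)
    return PairedTrajectories(
        pairs=pairs,
        unpaired_initialized=[ip.entries[i][0] for i in range(len(ip.entries))
                              if i not in used_rows],
        unpaired_manual=[manual.trajectories[j].electrode_id
                         for j in range(len(manual.trajectories)) if j not in used_cols],
    )


def validate_mapping(pairing: PairedTrajectories, bundle: ModelBundle) -> ValidationReport:
    """Apply the 2-sigma criterion to every pair and summarise.

    A pair passes when d_ep <= 2*sigma_ep and d_tp <= 2*sigma_tp (inclusive).
    A singleton mean trajectory has sigma = 0, so only an exact coordinate
    hit can pass; such pairs are flagged as degenerate in the report.
    ``fraction_mapped`` is the passing fraction over *paired* trajectories.
    """
    mts = bundle.mean_trajectories
    results = []
    for y, mp_id, ip_tr, mp_tr in pairing.pairs:
        mt: MeanTrajectory = mts[y - 1]
        d_ep = ip_tr.entry.distance_to(mp_tr.entry)
        d_tp = ip_tr.target.distance_to(mp_tr.target)
        passed = (d_ep <= 2.0 * mt.sigma_entry) and (d_tp <= 2.0 * mt.sigma_target)
        degenerate = mt.n_members == 1 or mt.sigma_entry == 0.0 or mt.sigma_target == 0.0
        if degenerate and not passed:
            logger.warning(
                "pair (mT%d, %s): singleton mean trajectory (sigma=0) auto-fails "
                "unless the distance is exactly 0", y, mp_id,
            )
        results.append(PairResult(
            mt_index=y, manual_electrode_id=mp_id,
            d_ep=d_ep, d_tp=d_tp,
            sigma_ep=mt.sigma_entry, sigma_tp=mt.sigma_target,
            passed=passed, degenerate_sigma=degenerate,
        ))
    fraction = (sum(r.passed for r in results) / len(results)) if results else 0.0
    return ValidationReport(
        pairs=results,
        fraction_mapped=fraction,
        unpaired_manual=pairing.unpaired_manual,
        unpaired_initialized=pairing.unpaired_initialized,
    )


def initialized_plan_to_plan(ip: InitializedPlan) -> Plan:
    """View an initialised plan as an ordinary Plan (for CSV export)."""
    return Plan(
        plan_id=f"IP_{ip.patient_id}",
        patient_id=ip.patient_id,
        trajectories=[tr for _, tr in ip.entries],
    )
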