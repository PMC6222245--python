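"""The persisted planning model: mean trajectories, strategies, zone config.

A model bundle is the product of mining one centre's retrospective plans.
It holds the ordered list of mean trajectories (whose positions define the
bit positions of every plan vector and strategy), the derived planning
strategies, and the zone configuration the descriptors were computed with.
Bundles are persisted as a single JSON document with an explicit schema
version so they are human-inspectable and diff-able.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .descriptor import Descriptor, ZoneConfig
from .errors import BundleValidationError
from .geometry import Point3

SCHEMA_VERSION = 1


@dataclass
class MeanTrajectory:
    """The centroid of one spatial sub-cluster of an exploratory pattern.

    ``sigma_entry`` / ``sigma_target`` are scalar dispersions: the RMS
    Euclidean (radial) distance of member entry / target points from the
    respective centroid, in mm.  They define the radius of the 2-sigma
    mapping-validation criterion.
    """

    descriptor: Descriptor
    index_u: int
    mean_entry: Point3
    mean_target: Point3
    sigma_entry: float
    sigma_target: float
    n_members: int
    member_refs: list[tuple[str, str]] = field(default_factory=list)  # (plan_id, electrode_id)

    def __post_init__(self) -> None:
        if self.index_u < 1:
            raise BundleValidationError(f"index_u must be >= 1, got {self.index_u}")
        if self.n_members < 1:
            raise BundleValidationError(f"n_members must be >= 1, got {self.n_members}")
        if self.sigma_entry < 0 or self.sigma_target < 0:
            raise BundleValidationError("sigma values must be >= 0")

    def to_dict(self) -> dict:
        return {
            "descriptor": {
                "entry_zone": self.descriptor.entry_zone,
                "target_zone": self.descriptor.target_zone,
            },
            "index_u": self.index_u,
            "mean_entry": list(self.mean_entry.to_array()),
            "mean_target": list(self.mean_target.to_array()),
            "sigma_entry": self.sigma_entry,
            "sigma_target": self.sigma_target,
            "n_members": self.n_members,
            "member_refs": [list(ref) for ref in self.member_refs],
        }

    @staticmethod
    def from_dict(d: dict) -> "MeanTrajectory":
        try:
            return MeanTrajectory(
                descriptor=Descriptor(
                    entry_zone=int(d["descriptor"]["entry_zone"]),
                    target_zone=int(d["descriptor"]["target_zone"]),
                ),
                index_u=int(d["index_u"]),
                mean_entry=Point3.from_array(d["mean_entry"]),
                mean_target=Point3.from_array(d["mean_target"]),
                sigma_entry=float(d["sigma_entry"]),
                sigma_target=float(d["sigma_target"]),
                n_members=int(d["n_members"]),
                member_refs=[(str(p), str(e)) for p, e in d.get("member_refs", [])],
            )
        except KeyError as exc:
            raise BundleValidationError(f"mean trajectory missing field {exc}") from exc


@dataclass
class Strategy:
    """A planning strategy: a reusable set of mean trajectories.

    ``bits[y]`` marks whether mean trajectory y belongs to the strategy; a
    bit is set only when at least two member plans contributed to that mean
    trajectory.
    """

    strategy_id: str
    bits: list[bool]
    member_plan_ids: list[str] = field(default_factory=list)
    name: str | None = None

    def to_dict(self) -> dict:
        return {
            "strategy_id": self.strategy_id,
            "bits": [bool(b) for b in self.bits],
            "member_plan_ids": list(self.member_plan_ids),
            "name": self.name,
        }

    @staticmethod
    def from_dict(d: dict) -> "Strategy":
        try:
            return Strategy(
                strategy_id=str(d["strategy_id"]),
                bits=[bool(b) for b in d["bits"]],
                member_plan_ids=[str(p) for p in d.get("member_plan_ids", [])],
                name=d.get("name"),
            )
        except KeyError as exc:
            raise BundleValidationError(f"strategy missing field {exc}") from exc


@dataclass
class ModelBundle:
    """Everything needed to initialise a plan for a new subject.

    The order of ``mean_trajectories`` is part of the model: position y
    (1-based) in this list is the bit position y of every plan vector and
    strategy, so the order is immutable once strategies exist.
    """

    mean_trajectories: list[MeanTrajectory]
    strategies: list[Strategy] = field(default_factory=list)
    zone_config: ZoneConfig = field(default_factory=ZoneConfig)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.mean_trajectories)
        for s in self.strategies:
            if len(s.bits) != n:
                raise BundleValidationError(
                    f"strategy {s.strategy_id!r}: bit-vector length {len(s.bits)} "
                    f"!= number of mean trajectories {n}"
                )

    def strategy_by_id(self, strategy_id: str) -> Strategy:
        for s in self.strategies:
            if s.strategy_id == strategy_id:
                return s
        raise KeyError(f"unknown strategy_id {strategy_id!r}")

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "mean_trajectories": [mt.to_dict() for mt in self.mean_trajectories],
            "strategies": [s.to_dict() for s in self.strategies],
            "zone_config": self.zone_config.to_dict(),
            "provenance": dict(self.provenance),
        }

    @staticmethod
    def from_dict(d: dict) -> "ModelBundle":
        version = d.get("schema_version")
        if version != SCHEMA_VERSION:
            raise BundleValidationError(
                f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})"
            )
        return ModelBundle(
            mean_trajectories=[
                MeanTrajectory.from_dict(m) for m in d.get("mean_trajectories", [])
            ],
            strategies=[Strategy.from_dict(s) for s in d.get("strategies", [])],
            zone_config=ZoneConfig.from_dict(d.get("zone_config", {})),
            provenance=dict(d.get("provenance", {})),
        )


def write_model(bundle: ModelBundle, path: str) -> None:
    bundle.validate()
    with open(path, "w") as fh:
        json.dump(bundle.to_dict(), fh, indent=2)
        fh.write("\n")


def read_model(path: str) -> ModelBundle:
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise BundleValidationError(f"{path}: not valid JSON: {exc}") from exc
    return ModelBundle.from_dict(d)
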