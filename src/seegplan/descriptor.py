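"""Trajectory descriptors: atlas labels along a trajectory reduced to
an (entry zone, target zone) pair.

A trajectory is regularly sampled along its arc; the raw atlas labels it
traverses are merged into clinically meaningful zones and reduced to the
descriptor d = [entry zone; target zone].  The descriptor is the unit of
similarity between trajectories of different patients: all trajectories
sharing a descriptor form one exploratory pattern.

The reduction applies three kinds of rules, all carried by :class:`ZoneConfig`:

* ``merge_map`` merges raw labels into composite zones (e.g. hippocampus and
  para-hippocampus as a single target, putamen folded into the insular zone,
  the occipital labels joined);
* ``ignore_labels`` are skipped during traversal (white matter, unknown);
* ``exclusion_zones`` mark trajectories that *terminate* in them (ventricles,
  brain stem, cerebellum) as outliers, excluded from pattern mining.

The clinical target of an electrode is not necessarily its end-point; it can
be any zone it crosses.  Here the target zone is the *deepest* traversed
member of the configurable target-zone set, which encodes that clinical
priority deterministically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .atlas import LabelVolume
from .errors import ContractError, SpaceMismatchError
from .geometry import Trajectory

logger = logging.getLogger(__name__)

#: Sentinel returned by :func:`extract_descriptor` for outlier trajectories.
OUTLIER = None


@dataclass(frozen=True, order=True)
class Descriptor:
    """The (entry zone, target zone) pair classifying a trajectory."""

    entry_zone: int
    target_zone: int


@dataclass
class LabelSequence:
    """Raw atlas labels sampled along a trajectory, ordered by arc-length."""

    arc_lengths: np.ndarray  # mm from the entry point, strictly increasing
    labels: np.ndarray  # raw label ids, same length

    def __post_init__(self) -> None:
        self.arc_lengths = np.asarray(self.arc_lengths, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.arc_lengths.shape != self.labels.shape:
            raise ContractError("arc_lengths and labels must have equal length")
        if len(self.arc_lengths) and np.any(np.diff(self.arc_lengths) <= 0):
            raise ContractError("arc_lengths must be strictly increasing")

    def __len__(self) -> int:
        return len(self.arc_lengths)


@dataclass
class ZoneConfig:
    """Zone vocabulary and reduction rules for descriptor extraction.

    ``merge_map`` maps raw label ids to zone ids; raw labels absent from the
    map are their own zone.  ``entry_zones`` / ``target_zones`` are the zone
    ids admitted as entry and (clinically relevant) target zones.
    """

    entry_zones: set[int] = field(default_factory=set)
    target_zones: set[int] = field(default_factory=set)
    merge_map: dict[int, int] = field(default_factory=dict)
    exclusion_zones: set[int] = field(default_factory=set)
    ignore_labels: set[int] = field(default_factory=set)

    def zone_of(self, raw_label: int) -> int:
        return self.merge_map.get(raw_label, raw_label)

    # -- JSON persistence ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "entry_zones": sorted(self.entry_zones),
            "target_zones": sorted(self.target_zones),
            "merge_map": {str(k): v for k, v in sorted(self.merge_map.items())},
            "exclusion_zones": sorted(self.exclusion_zones),
            "ignore_labels": sorted(self.ignore_labels),
        }

    @staticmethod
    def from_dict(d: dict) -> "ZoneConfig":
        return ZoneConfig(
            entry_zones=set(d.get("entry_zones", [])),
            target_zones=set(d.get("target_zones", [])),
            merge_map={int(k): int(v) for k, v in d.get("merge_map", {}).items()},
            exclusion_zones=set(d.get("exclusion_zones", [])),
            ignore_labels=set(d.get("ignore_labels", [])),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @staticmethod
    def load(path: str) -> "ZoneConfig":
        with open(path) as fh:
            return ZoneConfig.from_dict(json.load(fh))


def sample_labels(tr: Trajectory, atlas: LabelVolume, step: float = 1.0,
                  space: str | None = None) -> LabelSequence:
    """Sample atlas labels along a trajectory at regular arc-length intervals.

    Points are placed at arc-lengths 0, step, 2*step, ... from the entry
    point, plus the exact target end-point.  Labels are read by
    nearest-voxel lookup; points outside the grid get label 0.

    ``space``, when given, asserts the space the atlas lives in; a trajectory
    tagged otherwise raises :class:`SpaceMismatchError`.
    """
    if step <= 0:
        raise ContractError(f"sampling step must be positive, got {step}")
    if space is not None and tr.space != space:
        raise SpaceMismatchError(
            f"trajectory is in {tr.space!r} space but atlas is in {space!r} space"
        )
    length = tr.length
    arcs = np.arange(0.0, length, step)
    if len(arcs) == 0 or arcs[-1] < length:
        arcs = np.append(arcs, length)
    points = tr.entry.to_array()[None, :] + arcs[:, None] * tr.direction[None, :]
    return LabelSequence(arc_lengths=arcs, labels=atlas.labels_at(points))


def extract_descriptor(seq: LabelSequence, cfg: ZoneConfig) -> Descriptor | None:
    """Reduce a label sequence to its descriptor, or ``None`` for an outlier.

    A trajectory is an outlier when its deepest non-ignored raw label is an
    exclusion structure, when no admitted entry zone is traversed, or when no
    admitted target zone is traversed.
    """
    if len(seq) == 0:
        raise ContractError("empty label sequence")
    if cfg.ignore_labels:
        keep = ~np.isin(seq.labels, list(cfg.ignore_labels))
    else:
        keep = np.ones(len(seq), dtype=bool)
    raw = seq.labels[keep]
    if len(raw) == 0:
        return OUTLIER  # e.g. trajectory entirely in white matter
    if int(raw[-1]) in cfg.exclusion_zones:
        return OUTLIER  # terminates in an excluded structure
    zones = np.array([cfg.zone_of(int(l)) for l in raw])
    entry_zone: int | None = None
    for z in zones:
        if int(z) in cfg.entry_zones:
            entry_zone = int(z)
            break
    target_zone: int | None = None
    for z in zones[::-1]:  # deepest first
        if int(z) in cfg.target_zones:
            target_zone = int(z)
            break
    if entry_zone is None or target_zone is None:
        return OUTLIER
    return Descriptor(entry_zone=entry_zone, target_zone=target_zone)


def describe_trajectory(tr: Trajectory, atlas: LabelVolume, cfg: ZoneConfig,
                        step: float = 1.0, space: str | None = None) -> Descriptor | None:
    """Convenience: sample then extract in one call."""
    return extract_descriptor(sample_labels(tr, atlas, step=step, space=space), cfg)


# -- default zone configuration for Desikan-Killiany style label tables ------

_HIPPO_NAMES = ("hippocampus", "parahippocampal", "para-hippocampus", "parahippocampus")
_OCCIPITAL_NAMES = ("lingual", "cuneus", "precuneus", "pericalcarine")
_INSULA_NAMES = ("insula",)
_PUTAMEN_NAMES = ("putamen",)
_EXCLUSION_NAMES = ("ventricle", "brain-stem", "brainstem", "cerebellum")
_IGNORE_NAMES = ("white-matter", "white matter", "unknown", "wm-")


def _match(name: str, needles: tuple[str, ...]) -> bool:
    low = name.lower()
    return any(n in low for n in needles)


def default_zone_config(label_table: dict[int, str]) -> ZoneConfig:
    """Build a zone configuration from a label table by name-matching rules.

    When the table carries Desikan-Killiany style names, the standard merges
    are applied: hippocampus and para-hippocampus become a single target zone;
    lingual, cuneus, precuneus and pericalcarine are joined into one occipital
    zone; the putamen is folded into the insular zone.  Ventricles, brain stem
    and cerebellum become exclusion structures, and white matter / unknown are
    ignored during traversal.  Tables with none of these names (e.g. synthetic
    labels) get an identity merge map, empty exclusions, and every zone
    admitted as both entry and target.
    """
    cfg = ZoneConfig()
    ids_by_rule: dict[str, list[int]] = {"hippo": [], "occ": [], "insula": [], "putamen": []}
    for label_id, name in sorted(label_table.items()):
        if _match(name, _IGNORE_NAMES):
            cfg.ignore_labels.add(label_id)
        elif _match(name, _EXCLUSION_NAMES):
            cfg.exclusion_zones.add(label_id)
        elif _match(name, _HIPPO_NAMES):
            ids_by_rule["hippo"].append(label_id)
        elif _match(name, _OCCIPITAL_NAMES):
            ids_by_rule["occ"].append(label_id)
        elif _match(name, _INSULA_NAMES):
            ids_by_rule["insula"].append(label_id)
        elif _match(name, _PUTAMEN_NAMES):
            ids_by_rule["putamen"].append(label_id)
    cfg.ignore_labels.add(0)

    # composite zones take the smallest member id as their zone id
    for group in ("hippo", "occ"):
        ids = ids_by_rule[group]
        if len(ids) >= 2:
            zone = min(ids)
            for i in ids:
                cfg.merge_map[i] = zone
        elif len(ids) == 1:
            logger.warning(
                "zone merge rule %r skipped: only one matching label %s", group, ids
            )
    if ids_by_rule["putamen"]:
        if ids_by_rule["insula"]:
            insular_zone = min(ids_by_rule["insula"])
            for i in ids_by_rule["insula"] + ids_by_rule["putamen"]:
                cfg.merge_map[i] = insular_zone
        else:
            logger.warning("putamen->insula merge skipped: no insular label in table")

    # every remaining zone is admissible as entry and as target; the sets are
    # meant to be narrowed by the user to encode centre-specific practice
    zones = {
        cfg.zone_of(i)
        for i in label_table
        if i not in cfg.ignore_labels and i not in cfg.exclusion_zones
    }
    cfg.entry_zones = set(zones)
    cfg.target_zones = set(zones)
    return cfg
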