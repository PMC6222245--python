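"""Synthetic surgical-plan cohorts with known ground truth.

Real retrospective SEEG planning data cannot be shared, so this module
generates self-contained cohorts that emulate its structure: a small set of
planted mean trajectories arranged in a canonical average space, planning
strategies that are disjoint subsets of those trajectories, per-patient
plans drawn from a strategy with per-trajectory Gaussian positional noise
and optional per-trajectory dropout and multiplicity, invertible random
per-subject affines (so the pipeline's average-space normalisation is
genuinely exercised), and a block-structured label volume whose zones
contain the planted entry and target points.

Geometry: planted trajectories are vertical, one per 40 mm-wide column
along x.  The top slab of each column (z in [75, 100]) is that column's
entry zone; a deep block (z in [10, 40]) is its target zone; everything
else is a white-matter filler that descriptor extraction ignores.  Planted
entries sit at z = 85, targets at z = 25, so several millimetres of noise
never move a point out of its zone.

Ground truth is kept in a sidecar structure (and, on disk, a ``truth/``
directory) that the pipeline under test never reads.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .atlas import LabelVolume, write_label_volume
from .descriptor import Descriptor, ZoneConfig, describe_trajectory
from .errors import ContractError, GenerationError
from .geometry import AVERAGE, SUBJECT, AffineTransform, Plan, Point3, Trajectory
from .io import write_affine, write_plans

COLUMN_WIDTH_MM = 40.0
Y_HALF_EXTENT_MM = 40.0
Z_EXTENT_MM = 100.0
ENTRY_SLAB_MIN_Z = 75.0
TARGET_BLOCK_Z = (10.0, 40.0)
PLANTED_ENTRY_Z = 85.0
PLANTED_TARGET_Z = 25.0
WHITE_MATTER_LABEL = 1
ENTRY_LABEL_BASE = 100
TARGET_LABEL_BASE = 200


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; the seed is mandatory.

    Defaults give 4 disjoint strategies of 3 mean trajectories each, 40
    plans (10 per strategy), isotropic 2 mm positional noise, 10% dropout,
    and mild per-subject affines — a cohort on which the full pipeline
    should recover the planted model exactly.
    """

    seed: int
    n_strategies: int = 4
    mts_per_strategy: int = 3
    n_plans: int = 40
    noise_sigma_mm: float = 2.0
    plan_dropout_prob: float = 0.1
    multiplicity_map: dict[int, int] = field(default_factory=dict)  # planted mT idx -> copies/plan
    lateral_offset_mm: float = 10.0  # y-offset between same-plan copies
    affine_rot_deg: float = 5.0
    affine_scale: float = 0.05
    affine_trans_mm: float = 5.0
    voxel_size_mm: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.plan_dropout_prob <= 1.0):
            raise ContractError("plan_dropout_prob must be in [0, 1]")
        if self.noise_sigma_mm < 0:
            raise ContractError("noise_sigma_mm must be >= 0")
        if self.n_strategies < 1 or self.mts_per_strategy < 1 or self.n_plans < 1:
            raise ContractError("cohort counts must be >= 1")

    @property
    def n_planted_mts(self) -> int:
        return self.n_strategies * self.mts_per_strategy

    def to_dict(self) -> dict:
        d = vars(self).copy()
        d["multiplicity_map"] = {str(k): v for k, v in self.multiplicity_map.items()}
        return d

    @staticmethod
    def from_dict(d: dict) -> "CohortSpec":
        d = dict(d)
        d["multiplicity_map"] = {
            int(k): int(v) for k, v in d.get("multiplicity_map", {}).items()
        }
        return CohortSpec(**d)


@dataclass
class PlantedMeanTrajectory:
    index: int  # 0-based planted index (also the atlas column)
    descriptor: Descriptor
    entry: Point3
    target: Point3


@dataclass
class GroundTruth:
    """What the generator planted; never read by the pipeline under test."""

    planted_mts: list[PlantedMeanTrajectory]
    strategy_bits: list[list[bool]]  # over planted mT indices
    plan_strategy: dict[str, int]  # plan_id -> planted strategy index
    affines: dict[str, AffineTransform]  # patient_id -> subject->average

    def to_dict(self) -> dict:
        return {
            "planted_mts": [
                {
                    "index": p.index,
                    "entry_zone": p.descriptor.entry_zone,
                    "target_zone": p.descriptor.target_zone,
                    "entry": list(p.entry.to_array()),
                    "target": list(p.target.to_array()),
                }
                for p in self.planted_mts
            ],
            "strategy_bits": [[bool(b) for b in bits] for bits in self.strategy_bits],
            "plan_strategy": dict(self.plan_strategy),
            "affines": {k: v.matrix.tolist() for k, v in self.affines.items()},
        }


def planted_mean_trajectories(spec: CohortSpec) -> list[PlantedMeanTrajectory]:
    """Deterministic planted geometry: one vertical mT per atlas column."""
    out = []
    for c in range(spec.n_planted_mts):
        x = COLUMN_WIDTH_MM * (c + 0.5)
        out.append(PlantedMeanTrajectory(
            index=c,
            descriptor=Descriptor(
                entry_zone=ENTRY_LABEL_BASE + c,
                target_zone=TARGET_LABEL_BASE + c,
            ),
            entry=Point3(x, 0.0, PLANTED_ENTRY_Z),
            target=Point3(x, 0.0, PLANTED_TARGET_Z),
        ))
    return out


def planted_strategies(spec: CohortSpec) -> list[list[bool]]:
    """Disjoint supports: strategy s owns planted mTs [s*m, (s+1)*m)."""
    n = spec.n_planted_mts
    m = spec.mts_per_strategy
    return [
        [s * m <= y < (s + 1) * m for y in range(n)]
        for s in range(spec.n_strategies)
    ]


def generate_atlas(spec: CohortSpec) -> tuple[LabelVolume, ZoneConfig]:
    """Block-structured label volume + zone config covering the planted geometry.

    Fails fast if descriptor extraction on any noiseless planted trajectory
    disagrees with the planted descriptor.
    """
    v = spec.voxel_size_mm
    n_cols = spec.n_planted_mts
    x_extent = COLUMN_WIDTH_MM * n_cols
    nx = int(np.ceil(x_extent / v))
    ny = int(np.ceil(2 * Y_HALF_EXTENT_MM / v))
    nz = int(np.ceil(Z_EXTENT_MM / v))

    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = v
    aff[:3, 3] = [v / 2.0, -Y_HALF_EXTENT_MM + v / 2.0, v / 2.0]  # voxel centres
    vox2world = AffineTransform(aff)

    xs = v / 2.0 + v * np.arange(nx)
    zs = v / 2.0 + v * np.arange(nz)
    col = np.minimum((xs // COLUMN_WIDTH_MM).astype(int), n_cols - 1)

    labels = np.full((nx, ny, nz), WHITE_MATTER_LABEL, dtype=np.int32)
    entry_z = zs >= ENTRY_SLAB_MIN_Z
    target_z = (zs >= TARGET_BLOCK_Z[0]) & (zs <= TARGET_BLOCK_Z[1])
    for i in range(nx):
        labels[i, :, entry_z] = ENTRY_LABEL_BASE + col[i]
        labels[i, :, target_z] = TARGET_LABEL_BASE + col[i]

    table = {WHITE_MATTER_LABEL: "white_matter_filler"}
    for c in range(n_cols):
        table[ENTRY_LABEL_BASE + c] = f"entry_zone_{c}"
        table[TARGET_LABEL_BASE + c] = f"target_zone_{c}"
    volume = LabelVolume(labels=labels, vox2world=vox2world, label_table=table)

    cfg = ZoneConfig(
        entry_zones={ENTRY_LABEL_BASE + c for c in range(n_cols)},
        target_zones={TARGET_LABEL_BASE + c for c in range(n_cols)},
        merge_map={},
        exclusion_zones=set(),
        ignore_labels={0, WHITE_MATTER_LABEL},
    )

    for planted in planted_mean_trajectories(spec):
        tr = Trajectory(
            plan_id="check", electrode_id=f"mt{planted.index}",
            entry=planted.entry, target=planted.target, space=AVERAGE,
        )
        got = describe_trajectory(tr, volume, cfg, step=1.0, space=AVERAGE)
        if got != planted.descriptor:
            raise GenerationError(
                f"planted trajectory {planted.index} extracts descriptor {got}, "
                f"expected {planted.descriptor}"
            )
    return volume, cfg


def _random_affine(rng: np.random.Generator, spec: CohortSpec) -> AffineTransform:
    """Small random rotation + isotropic scale + translation (subject->average)."""
    angle = np.radians(rng.uniform(-spec.affine_rot_deg, spec.affine_rot_deg))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    scale = 1.0 + rng.uniform(-spec.affine_scale, spec.affine_scale)
    m = np.eye(4)
    m[:3, :3] = rot * scale
    m[:3, 3] = rng.uniform(-spec.affine_trans_mm, spec.affine_trans_mm, size=3)
    return AffineTransform(m)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[Plan], dict[str, AffineTransform], GroundTruth]:
    """Draw a cohort of subject-space plans from the planted model.

    Each plan is assigned a strategy round-robin; each of the strategy's
    mean trajectories is included with probability 1 - dropout (at least one
    is always kept, so every plan is non-empty), replicated per the
    multiplicity map with lateral y-offsets, jittered with isotropic
    Gaussian noise in the average space, and mapped into the subject space
    through the inverse of a random per-subject affine.  All randomness
    derives from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    planted = planted_mean_trajectories(spec)
    strategies = planted_strategies(spec)

    plans: list[Plan] = []
    affines: dict[str, AffineTransform] = {}
    plan_strategy: dict[str, int] = {}
    for j in range(spec.n_plans):
        patient_id = f"P{j:03d}"
        plan_id = f"plan{j:03d}"
        s = j % spec.n_strategies
        affine = _random_affine(rng, spec)
        inv = affine.inverse()
        owned = [y for y, bit in enumerate(strategies[s]) if bit]
        kept = [y for y in owned if rng.random() >= spec.plan_dropout_prob]
        if not kept:
            kept = [owned[0]]  # a plan always has at least one electrode
        trajectories = []
        for y in kept:
            m = spec.multiplicity_map.get(y, 1)
            for r in range(m):
                offset = np.array([0.0, r * spec.lateral_offset_mm, 0.0])
                ep = planted[y].entry.to_array() + offset
                tp = planted[y].target.to_array() + offset
                if spec.noise_sigma_mm > 0:
                    ep = ep + rng.normal(0.0, spec.noise_sigma_mm, size=3)
                    tp = tp + rng.normal(0.0, spec.noise_sigma_mm, size=3)
                electrode_id = f"E{y}" if m == 1 else f"E{y}_{r}"
                trajectories.append(Trajectory(
                    plan_id=plan_id,
                    electrode_id=electrode_id,
                    entry=inv.apply(Point3.from_array(ep)),
                    target=inv.apply(Point3.from_array(tp)),
                    space=SUBJECT,
                ))
        plans.append(Plan(plan_id=plan_id, patient_id=patient_id,
                          trajectories=trajectories))
        affines[patient_id] = affine
        plan_strategy[plan_id] = s

    truth = GroundTruth(
        planted_mts=planted,
        strategy_bits=strategies,
        plan_strategy=plan_strategy,
        affines=affines,
    )
    return plans, affines, truth


def write_cohort(spec: CohortSpec, out_dir: str) -> None:
    """Materialise a cohort on disk in the formats the CLI pipeline consumes.

    Layout: ``plans.csv``, ``xfm/<patient_id>.mat``, ``atlas.nii`` +
    ``atlas_lut.txt``, ``zones.json``, ``spec.json``, and the ground truth
    under ``truth/`` (which the pipeline never reads).
    """
    volume, cfg = generate_atlas(spec)
    plans, affines, truth = generate_cohort(spec)
    os.makedirs(out_dir, exist_ok=True)
    os.makedirs(os.path.join(out_dir, "xfm"), exist_ok=True)
    os.makedirs(os.path.join(out_dir, "truth"), exist_ok=True)
    write_plans(plans, os.path.join(out_dir, "plans.csv"))
    for patient_id, affine in affines.items():
        write_affine(affine, os.path.join(out_dir, "xfm", f"{patient_id}.mat"))
    write_label_volume(volume, os.path.join(out_dir, "atlas.nii"),
                       os.path.join(out_dir, "atlas_lut.txt"))
    cfg.save(os.path.join(out_dir, "zones.json"))
    with open(os.path.join(out_dir, "spec.json"), "w") as fh:
        json.dump(spec.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(out_dir, "truth", "truth.json"), "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
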