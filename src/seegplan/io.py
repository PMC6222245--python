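"""Readers and writers for trajectory tables and affine registration files.

Trajectory tables are CSV with the header
``patient_id,plan_id,electrode_id,ep_x,ep_y,ep_z,tp_x,tp_y,tp_z`` and
coordinates in mm (subject space unless stated otherwise).  Affines are
plain-text 4x4 matrices, whitespace-separated, row-major, mapping
homogeneous RAS mm coordinates from subject to average space.  Native
neuroimaging registration formats (.xfm, .lta) can be converted to this
dialect by dumping their 4x4 matrix as text.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AffineFormatError, ContractError, TableParseError
from .geometry import AffineTransform, Plan, Point3, Trajectory

TRAJECTORY_COLUMNS = [
    "patient_id", "plan_id", "electrode_id",
    "ep_x", "ep_y", "ep_z", "tp_x", "tp_y", "tp_z",
]
_COORD_COLUMNS = TRAJECTORY_COLUMNS[3:]


def read_plans(path: str, space: str = "subject") -> list[Plan]:
    """Parse a trajectory table into one Plan per distinct (patient_id, plan_id).

    Plans are returned in order of first appearance.  Rows with a missing
    column, a non-numeric coordinate, a duplicate (plan_id, electrode_id)
    pair, or a zero-length trajectory raise :class:`TableParseError` naming
    the offending row.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise TableParseError(f"{path}: empty file (no header)") from exc
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing column(s) {missing}")

    plans: dict[tuple[str, str], Plan] = {}
    trajectories: dict[tuple[str, str], list[Trajectory]] = {}
    order: list[tuple[str, str]] = []
    seen_electrodes: set[tuple[str, str]] = set()
    for row_idx, row in df.iterrows():
        rowno = int(row_idx) + 2  # 1-based, after the header line
        coords = {}
        for col in _COORD_COLUMNS:
            try:
                coords[col] = float(row[col])
            except (TypeError, ValueError) as exc:
                raise TableParseError(
                    f"{path}: row {rowno}: non-numeric {col}={row[col]!r}"
                ) from exc
        patient_id = str(row["patient_id"])
        plan_id = str(row["plan_id"])
        electrode_id = str(row["electrode_id"])
        if (plan_id, electrode_id) in seen_electrodes:
            raise TableParseError(
                f"{path}: row {rowno}: duplicate (plan_id, electrode_id) "
                f"({plan_id!r}, {electrode_id!r})"
            )
        seen_electrodes.add((plan_id, electrode_id))
        try:
            tr = Trajectory(
                plan_id=plan_id,
                electrode_id=electrode_id,
                entry=Point3(coords["ep_x"], coords["ep_y"], coords["ep_z"]),
                target=Point3(coords["tp_x"], coords["tp_y"], coords["tp_z"]),
                space=space,
            )
        except ContractError as exc:
            raise TableParseError(f"{path}: row {rowno}: {exc}") from exc
        key = (patient_id, plan_id)
        if key not in trajectories:
            trajectories[key] = []
            order.append(key)
        trajectories[key].append(tr)

    for patient_id, plan_id in order:
        plans[(patient_id, plan_id)] = Plan(
            plan_id=plan_id,
            patient_id=patient_id,
            trajectories=trajectories[(patient_id, plan_id)],
        )
    return [plans[key] for key in order]


def write_plans(plans: list[Plan], path: str) -> None:
    rows = []
    for plan in plans:
        for tr in plan.trajectories:
            rows.append({
                "patient_id": plan.patient_id,
                "plan_id": plan.plan_id,
                "electrode_id": tr.electrode_id,
                "ep_x": tr.entry.x, "ep_y": tr.entry.y, "ep_z": tr.entry.z,
                "tp_x": tr.target.x, "tp_y": tr.target.y, "tp_z": tr.target.z,
            })
    pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS).to_csv(path, index=False)


def read_affine(path: str) -> AffineTransform:
    """Read a whitespace-separated 4x4 affine text file and validate it."""
    try:
        m = np.loadtxt(path, dtype=float)
    except ValueError as exc:
        raise AffineFormatError(f"{path}: non-numeric affine entry: {exc}") from exc
    if m.shape != (4, 4):
        raise AffineFormatError(f"{path}: expected a 4x4 matrix, got shape {m.shape}")
    try:
        return AffineTransform(m)
    except AffineFormatError as exc:
        raise AffineFormatError(f"{path}: {exc}") from exc


def write_affine(t: AffineTransform, path: str) -> None:
    np.savetxt(path, t.matrix, fmt="%.17g")
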