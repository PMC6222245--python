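"""Labelled atlas volumes: an integer label grid plus its voxel-to-world affine.

The label volume plays the role of a parcellation (e.g. a Desikan-Killiany
style cortical atlas) and is read along trajectories to classify which brain
zones an electrode traverses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import BundleValidationError
from .geometry import AffineTransform


@dataclass
class LabelVolume:
    """3-D integer label grid with a voxel-index -> world-mm affine.

    ``label_table`` maps every label id present in the grid (except 0, the
    conventional unknown/background id) to a human-readable name.
    """

    labels: np.ndarray
    vox2world: AffineTransform
    label_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise BundleValidationError(
                f"label grid must be 3-D, got {self.labels.ndim}-D"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise BundleValidationError("label grid must hold integers")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise BundleValidationError(
                f"label ids present in grid but absent from label table: {sorted(missing)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 3) world-mm points to continuous voxel indices."""
        return self.vox2world.inverse().apply_array(points)

    def labels_at(self, points: np.ndarray) -> np.ndarray:
        """Nearest-voxel label lookup for (n, 3) world points; 0 outside the grid."""
        vox = np.rint(self.world_to_voxel(np.atleast_2d(points))).astype(int)
        shape = np.array(self.shape)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        out = np.zeros(len(vox), dtype=self.labels.dtype)
        if np.any(inside):
            idx = vox[inside]
            out[inside] = self.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
        return out


def read_label_volume(nifti_path: str, lut_path: str) -> LabelVolume:
    """Load a NIfTI-1 integer volume and a two-column ``label_id label_name`` LUT."""
    img = nib.load(nifti_path)
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded):
            raise BundleValidationError(
                f"{nifti_path}: voxel values are not integer labels"
            )
        data = rounded.astype(np.int32)
    return LabelVolume(
        labels=data,
        vox2world=AffineTransform(img.affine),
        label_table=read_label_table(lut_path),
    )


def write_label_volume(vol: LabelVolume, nifti_path: str, lut_path: str) -> None:
    img = nib.Nifti1Image(vol.labels.astype(np.int32), vol.vox2world.matrix)
    nib.save(img, nifti_path)
    write_label_table(vol.label_table, lut_path)


def read_label_table(path: str) -> dict[int, str]:
    table: dict[int, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(maxsplit=1)
            if len(parts) != 2:
                raise BundleValidationError(
                    f"{path}:{lineno}: expected 'label_id label_name', got {line!r}"
                )
            try:
                label_id = int(parts[0])
            except ValueError as exc:
                raise BundleValidationError(
                    f"{path}:{lineno}: non-integer label id {parts[0]!r}"
                ) from exc
            table[label_id] = parts[1]
    return table


def write_label_table(table: dict[int, str], path: str) -> None:
    with open(path, "w") as fh:
        for label_id in sorted(table):
            fh.write(f"{label_id} {table[label_id]}\n")
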