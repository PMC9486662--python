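"""Voxel-volume containers: probabilistic tract atlas and binary lesion masks.

All volumes live on a common isotropic grid (0-based voxel indices, RAS
world axes, the affine carried by every object).  Registration and
normalization are out of scope: inputs are assumed co-registered, and a
grid-compatibility check runs before any voxelwise operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["TractAtlas", "LesionMask", "check_same_grid"]


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


@dataclass
class TractAtlas:
    """Named probabilistic white-matter tract maps on a shared grid.

    ``tracts`` maps tract names to float arrays with values in [0, 1]
    (probability that a voxel belongs to the tract across the healthy
    reference population).  ``patches`` holds auxiliary binary cortical
    regions used to place lesion cores.
    """

    tracts: dict[str, np.ndarray]
    voxel_size_mm: float
    patches: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {t.shape for t in self.tracts.values()}
        if len(shapes) > 1:
            raise ValueError("tract maps must share a grid")
        for name, arr in self.tracts.items():
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"tract {name!r}: values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.tracts.values())).shape

    def tract_mask(self, name: str, threshold: float = 0.0) -> np.ndarray:
        """Binary extent of a tract: voxels with probability > threshold."""
        return self.tracts[name] > threshold

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        aff = _affine(self.voxel_size_mm)
        for name, arr in self.tracts.items():
            img = nib.Nifti1Image(arr.astype(np.float32), aff)
            nib.save(img, directory / f"tract_{name}.nii.gz")
        for name, arr in self.patches.items():
            img = nib.Nifti1Image(arr.astype(np.uint8), aff)
            nib.save(img, directory / f"patch_{name}.nii.gz")

    @classmethod
    def load(cls, directory: str | Path) -> "TractAtlas":
        directory = Path(directory)
        tracts, patches = {}, {}
        voxel = None
        for path in sorted(directory.glob("tract_*.nii.gz")):
            img = nib.load(path)
            tracts[path.name[len("tract_"):-len(".nii.gz")]] = np.asarray(
                img.dataobj, dtype=np.float32)
            voxel = float(img.header.get_zooms()[0])
        for path in sorted(directory.glob("patch_*.nii.gz")):
            img = nib.load(path)
            patches[path.name[len("patch_"):-len(".nii.gz")]] = (
                np.asarray(img.dataobj) > 0)
        if not tracts:
            raise FileNotFoundError(f"no tract_*.nii.gz under {directory}")
        return cls(tracts=tracts, voxel_size_mm=voxel, patches=patches)


@dataclass
class LesionMask:
    """Binary lesion mask for one patient."""

    data: np.ndarray
    voxel_size_mm: float
    patient_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if not self.data.any():
            raise ValueError(f"lesion mask {self.patient_id!r} is empty")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def volume_cc(self) -> float:
        return float(self.data.sum() * (self.voxel_size_mm / 10.0) ** 3)

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.uint8),
                              _affine(self.voxel_size_mm))
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path, patient_id: str | None = None) -> "LesionMask":
        img = nib.load(str(path))
        pid = patient_id or Path(path).name.split(".")[0]
        return cls(data=np.asarray(img.dataobj) > 0,
                   voxel_size_mm=float(img.header.get_zooms()[0]),
                   patient_id=pid)


def check_same_grid(*shapes_or_objects) -> tuple[int, ...]:
    """Validate that all arguments share one grid shape; return it."""
    shapes = []
    for obj in shapes_or_objects:
        shapes.append(obj.shape if hasattr(obj, "shape") else tuple(obj))
    ref = shapes[0]
    for s in shapes[1:]:
        if tuple(s) != tuple(ref):
            raise ValueError(f"grid mismatch: {s} vs {ref}")
    return tuple(ref)
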