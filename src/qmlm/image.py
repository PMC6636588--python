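"""Volumetric image and atlas containers.

A :class:`VolumetricImage` is the universal carrier for every map and mask in
the pipeline: a 3D (or 4D, for multi-echo series) scalar grid together with a
voxel-to-world affine.  All images belonging to one analysis are required to
live on the same grid; operations check this and refuse to mix grids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["VolumetricImage", "Atlas", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Raised when two volumes do not share grid shape and affine."""


@dataclass
class VolumetricImage:
    """A scalar grid plus its voxel-to-world affine.

    Parameters
    ----------
    data:
        3D array (or 4D for a multi-volume series, last axis = volume index).
    affine:
        4x4 voxel-to-world matrix (NIfTI convention, mm).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be 3D or 4D")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm, one per spatial axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def same_grid(self, other: "VolumetricImage") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def check_grid(self, other: "VolumetricImage", what: str = "volume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what}: grid mismatch (shape {other.shape} vs {self.shape} "
                f"or differing affine)"
            )

    def with_data(self, data: np.ndarray) -> "VolumetricImage":
        """New image on the same grid with different voxel data."""
        return VolumetricImage(np.asarray(data), self.affine.copy())

    # ---- I/O -------------------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float64), self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VolumetricImage":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj).astype(np.float64), img.affine)

    @classmethod
    def isotropic(cls, data: np.ndarray, voxel_size_mm: float) -> "VolumetricImage":
        aff = np.diag([voxel_size_mm] * 3 + [1.0])
        return cls(np.asarray(data), aff)


# Lobe names an atlas may carry.  Cortical lobes participate in concordance;
# excluded labels mark non-parenchymal or non-cortical tissue that the
# parenchyma filter removes findings from.
CORTICAL_LOBES = ("frontal", "parietal", "temporal", "occipital")
EXCLUDED_LOBES = ("background", "csf", "ventricle", "brainstem", "cerebellum")


@dataclass
class Atlas:
    """Integer label volume plus a table mapping label -> (lobe, side).

    ``table`` columns: ``label`` (int), ``lobe`` (str), ``side`` (str; one of
    ``left``/``right``/``none``).  ``gm_mask`` optionally marks cortical gray
    matter for the distance-to-cortex rule of the parenchyma filter.
    """

    labels: VolumetricImage
    table: pd.DataFrame
    gm_mask: VolumetricImage | None = None

    def __post_init__(self) -> None:
        required = {"label", "lobe", "side"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"atlas table must have columns {sorted(required)}")
        self._lookup = {
            int(r.label): (str(r.lobe), str(r.side)) for r in self.table.itertuples()
        }

    def region_of(self, label: int) -> tuple[str, str]:
        try:
            return self._lookup[int(label)]
        except KeyError:
            raise KeyError(f"label {label} not in atlas table") from None

    def is_excluded(self, label: int) -> bool:
        lobe, _ = self.region_of(label)
        return lobe in EXCLUDED_LOBES

    def save(self, stem: str | Path) -> None:
        """Write ``<stem>.nii.gz`` label volume and ``<stem>.tsv`` table."""
        stem = Path(stem)
        self.labels.save(stem.with_suffix(".nii.gz"))
        self.table.to_csv(stem.with_suffix(".tsv"), sep="\t", index=False)
        if self.gm_mask is not None:
            self.gm_mask.save(stem.parent / (stem.name + "_gm.nii.gz"))

    @classmethod
    def load(cls, stem: str | Path) -> "Atlas":
        stem = Path(stem)
        labels = VolumetricImage.load(stem.with_suffix(".nii.gz"))
        table = pd.read_csv(stem.with_suffix(".tsv"), sep="\t")
        gm_path = stem.parent / (stem.name + "_gm.nii.gz")
        gm = VolumetricImage.load(gm_path) if gm_path.exists() else None
        return cls(labels, table, gm)


def save_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())
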