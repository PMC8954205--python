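"""Core in-memory containers: intensity volumes and integer atlas volumes.

A :class:`Volume` is a 3-D grid of non-negative activity values (arbitrary
units) on the ``(x, y, z)`` axes, with ``z`` the axial (slice) axis.  An
:class:`AtlasVolume` is an integer label grid on the same axes mapping voxels
to named anatomical regions.  NIfTI-1 is the on-disk form for both; all
indexing in the codebase is 0-based and half-open, conversions happen only
here at I/O time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "AtlasVolume"]


@dataclass
class Volume:
    """A 3-D non-negative intensity grid with voxel size metadata.

    Parameters
    ----------
    data:
        Array of shape ``(nx, ny, nz)``; ``nz`` indexes axial slices.
    voxel_size:
        Physical voxel edge lengths in mm.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        if np.any(self.data < 0):
            raise ValueError("volume intensities must be non-negative")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive reals, got {self.voxel_size}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff

    def to_nifti(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine())
        img.header.set_zooms(self.voxel_size)
        nib.save(img, str(path))
        return path

    @classmethod
    def from_nifti(cls, path: str | Path) -> "Volume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        # Guard against tiny negative values from float32 round-trips.
        data = np.clip(data, 0.0, None)
        return cls(data=data, voxel_size=zooms)


@dataclass
class AtlasVolume:
    """Integer-labelled region grid aligned to the phantoms it is paired with.

    ``region_names`` maps each nonzero label to a region name.  Bilateral
    structures carry ``_l`` / ``_r`` suffixes; :meth:`labels_for` resolves a
    base name such as ``"hippocampus"`` to both lateralized labels, so effect
    maps and crop-region lists can use either form.
    """

    labels: np.ndarray
    region_names: dict[int, str] = field(default_factory=dict)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if np.any(self.labels < 0):
            raise ValueError("atlas labels must be non-negative")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.region_names)
        if missing:
            raise ValueError(f"labels without a region name: {sorted(missing)}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def names(self) -> list[str]:
        return [self.region_names[k] for k in sorted(self.region_names)]

    def labels_for(self, name: str) -> list[int]:
        """Labels whose region name equals ``name`` or ``name`` + ``_l``/``_r``."""
        hits = [k for k, v in self.region_names.items()
                if v == name or v in (name + "_l", name + "_r")]
        if not hits:
            raise KeyError(f"region {name!r} not in atlas (known: {self.names})")
        return sorted(hits)

    def mask(self, name: str) -> np.ndarray:
        return np.isin(self.labels, self.labels_for(name))

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def to_nifti(self, path: str | Path, names_path: str | Path | None = None) -> Path:
        path = Path(path)
        aff = np.diag(list(self.voxel_size) + [1.0])
        img = nib.Nifti1Image(self.labels.astype(np.int16), aff)
        img.header.set_zooms(self.voxel_size)
        nib.save(img, str(path))
        if names_path is not None:
            with open(names_path, "w", newline="") as fh:
                w = csv.writer(fh, delimiter="\t")
                w.writerow(["label", "name"])
                for k in sorted(self.region_names):
                    w.writerow([k, self.region_names[k]])
        return path

    @classmethod
    def from_nifti(cls, path: str | Path, names_path: str | Path) -> "AtlasVolume":
        img = nib.load(str(path))
        labels = np.asarray(img.dataobj).astype(np.int32)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        names: dict[int, str] = {}
        with open(names_path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                names[int(row["label"])] = row["name"]
        return cls(labels=labels, region_names=names, voxel_size=zooms)
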