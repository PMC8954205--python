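"""Atlas-driven cropping of volumes to the limbic-system axial slab.

Cropping keeps the full in-plane extent and restricts the axial axis to the
slab of slices containing the requested regions (plus an optional margin),
mirroring a slices-of-interest selection around the hippocampus, amygdala,
thalamus and putamen.  The :class:`CropBox` is returned alongside the crop so
results computed on the cropped grid (e.g. activation maps) can be embedded
back into whole-volume coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import AtlasVolume, Volume

__all__ = ["CropBox", "LIMBIC_REGIONS", "limbic_crop_box", "crop", "embed"]

LIMBIC_REGIONS: tuple[str, ...] = ("hippocampus", "amygdala", "thalamus", "putamen")


@dataclass(frozen=True)
class CropBox:
    """Half-open, 0-based voxel index box ``[start, stop)`` per axis."""

    start: tuple[int, int, int]
    stop: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.start) != 3 or len(self.stop) != 3:
            raise ValueError("start and stop must be length-3")
        for a, b in zip(self.start, self.stop):
            if a < 0 or b <= a:
                raise ValueError(f"invalid box: start {self.start}, stop {self.stop}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(b - a for a, b in zip(self.start, self.stop))  # type: ignore

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))  # type: ignore

    @classmethod
    def whole(cls, dims: tuple[int, int, int]) -> "CropBox":
        return cls(start=(0, 0, 0), stop=tuple(dims))  # type: ignore[arg-type]


def limbic_crop_box(atlas: AtlasVolume,
                    regions: tuple[str, ...] = LIMBIC_REGIONS,
                    margin: int = 0) -> CropBox:
    """Tightest axial slab covering the union of the named regions.

    The in-plane axes are kept whole; the axial range is the union of the
    regions' voxel z-extents, expanded by ``margin`` slices and clipped to the
    volume.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    nx, ny, nz = atlas.dims
    zmin, zmax = nz, -1
    for name in regions:
        mask = atlas.mask(name)  # raises KeyError naming an unknown region
        zs = np.nonzero(mask.any(axis=(0, 1)))[0]
        if zs.size == 0:
            raise ValueError(f"region {name!r} is empty in the atlas")
        zmin = min(zmin, int(zs[0]))
        zmax = max(zmax, int(zs[-1]))
    start_z = max(0, zmin - margin)
    stop_z = min(nz, zmax + 1 + margin)
    return CropBox(start=(0, 0, start_z), stop=(nx, ny, stop_z))


def crop(vol: Volume, box: CropBox) -> tuple[Volume, CropBox]:
    """Extract the sub-volume inside ``box``; echoes the box for back-mapping."""
    for a, b, d in zip(box.start, box.stop, vol.dims):
        if b > d:
            raise ValueError(f"box {box} exceeds volume dims {vol.dims}")
    sub = vol.data[box.slices].copy()
    return Volume(data=sub, voxel_size=vol.voxel_size), box


def embed(data: np.ndarray, box: CropBox,
          dims: tuple[int, int, int]) -> np.ndarray:
    """Place a cropped-grid array back at ``box.start`` in a zero whole grid."""
    if tuple(data.shape) != box.shape:
        raise ValueError(f"data shape {data.shape} != box shape {box.shape}")
    out = np.zeros(dims, dtype=np.asarray(data).dtype)
    out[box.slices] = data
    return out
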