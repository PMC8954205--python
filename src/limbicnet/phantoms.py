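"""Synthetic FDG-PET-like phantom cohorts with a matching anatomical atlas.

The generator stands in for an access-gated clinical cohort.  It produces:

* a geometric brain atlas — an ellipsoidal brain containing disjoint
  ellipsoidal subregions (lateralized where anatomy is bilateral) for the
  middle frontal and middle temporal gyri, insula, hippocampus, amygdala,
  thalamus, putamen and caudate, with the remaining brain voxels labelled
  cortex;
* clean phantoms — piecewise-constant regional uptake with per-subject
  multiplicative variation, and class-dependent regional hypometabolism
  (the AD class has each affected region's mean reduced by a stated
  fraction);
* degraded acquisitions — per-slice 2-D Gaussian blur of scanner-dependent
  width, additive intensity-scaled Gaussian noise, and scanner-dependent
  slice counts, emulating multi-scanner variability.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .restoration import blur_slice, make_psf
from .volume import AtlasVolume, Volume

__all__ = [
    "ScannerProfile",
    "CohortSpec",
    "SubjectRecord",
    "AtlasSizingError",
    "REGION_VALUES",
    "DEFAULT_EFFECT_MAP",
    "DEFAULT_SCANNERS",
    "build_atlas",
    "make_phantom",
    "degrade",
    "generate_cohort",
]


class AtlasSizingError(ValueError):
    """Raised when a region cannot be rasterized at the requested dims."""


@dataclass(frozen=True)
class ScannerProfile:
    """Acquisition characteristics of one scanner model.

    ``blur_sigma`` is the Gaussian PSF width in voxels, ``noise_sd`` the
    additive noise level as a fraction of the mean in-brain intensity, and
    ``n_slices`` the axial slice count of the stored image.
    """

    name: str
    blur_sigma: float = 2.0
    noise_sd: float = 0.10
    n_slices: int = 40

    def __post_init__(self) -> None:
        if self.blur_sigma < 0 or self.noise_sd < 0 or self.n_slices < 1:
            raise ValueError(f"invalid scanner profile {self!r}")


# Desk-scale analogues of the slice-thickness / noise spread seen across the
# nine clinical scanner models the study drew from.
DEFAULT_SCANNERS: tuple[tuple[ScannerProfile, float], ...] = (
    (ScannerProfile("hrrt", blur_sigma=1.5, noise_sd=0.12, n_slices=40), 0.4),
    (ScannerProfile("hr_plus", blur_sigma=2.0, noise_sd=0.10, n_slices=32), 0.4),
    (ScannerProfile("accel", blur_sigma=2.5, noise_sd=0.10, n_slices=24), 0.2),
)

# Relative regional hypometabolism of the AD class: strongest in the medial
# temporal lobe, milder in neocortical and deep-gray regions.
DEFAULT_EFFECT_MAP: dict[str, float] = {
    "hippocampus": 0.20,
    "amygdala": 0.15,
    "middle_temporal": 0.15,
    "middle_frontal": 0.10,
    "insula": 0.10,
    "thalamus": 0.08,
    "putamen": 0.08,
    "caudate": 0.08,
}


@dataclass
class CohortSpec:
    """Recipe for a two-class cohort, reproducible from ``seed``."""

    n_control: int = 155
    n_ad: int = 66
    dims: tuple[int, int, int] = (64, 64, 40)
    effect_map: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_MAP))
    scanner_profiles: tuple[tuple[ScannerProfile, float], ...] = DEFAULT_SCANNERS
    subject_sd: float = 0.05  # per-region log-normal variation
    noise_model: str = "gaussian"  # gaussian | poisson
    poisson_counts: float = 1e4  # expected total counts when noise_model=poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_ad < 1:
            raise ValueError("class sizes must be positive")
        if any(not (0 <= e < 1) for e in self.effect_map.values()):
            raise ValueError("effect-map reductions must lie in [0, 1)")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


@dataclass(frozen=True)
class SubjectRecord:
    id: str
    label: str  # control | ad
    volume_path: str
    scanner: str


# Region layout in brain-normalized coordinates u = (index - center)/semi_axis,
# with x the lateral axis (mirrored for the left hemisphere), y anterior+, and
# z superior+.  Centers/radii were chosen so all bounding boxes are pairwise
# disjoint and every region clears the brain surface.
_REGION_GEOMETRY: dict[str, tuple[tuple[float, float, float],
                                  tuple[float, float, float]]] = {
    "thalamus": ((0.20, -0.10, -0.13), (0.15, 0.16, 0.16)),
    "caudate": ((0.20, 0.32, 0.08), (0.15, 0.16, 0.15)),
    "putamen": ((0.50, 0.10, -0.12), (0.14, 0.16, 0.15)),
    "hippocampus": ((0.40, -0.48, -0.22), (0.17, 0.18, 0.16)),
    "amygdala": ((0.40, -0.10, -0.45), (0.16, 0.15, 0.15)),
    "middle_temporal": ((0.72, -0.30, -0.15), (0.13, 0.17, 0.16)),
    "insula": ((0.77, 0.25, 0.05), (0.12, 0.16, 0.15)),
    "middle_frontal": ((0.40, 0.55, 0.40), (0.16, 0.17, 0.16)),
}

# Baseline regional uptake (arbitrary activity units).
REGION_VALUES: dict[str, float] = {
    "cortex": 1.00,
    "thalamus": 1.15,
    "caudate": 1.10,
    "putamen": 1.15,
    "hippocampus": 0.95,
    "amygdala": 0.95,
    "middle_temporal": 1.00,
    "insula": 1.05,
    "middle_frontal": 1.00,
}

# Brain semi-axes as fractions of the half-dims: the brain fills most of the
# field of view, as in template-space PET.
_BRAIN_SEMI = (0.86, 0.90, 0.82)


def build_atlas(dims: tuple[int, int, int] = (64, 64, 40),
                voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
                ) -> AtlasVolume:
    """Rasterize the geometric atlas at the given grid dims.

    Raises :class:`AtlasSizingError` naming the first region that rasterizes
    to zero voxels when the grid is too small.
    """
    if len(dims) != 3 or any(d < 16 for d in dims):
        raise ValueError(f"each dim must be >= 16, got {dims}")
    nx, ny, nz = dims
    center = (np.array(dims) - 1) / 2.0
    semi = np.array([_BRAIN_SEMI[i] * dims[i] / 2.0 for i in range(3)])

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    u = np.stack([(ii - center[0]) / semi[0],
                  (jj - center[1]) / semi[1],
                  (kk - center[2]) / semi[2]])
    brain = (u**2).sum(axis=0) <= 1.0

    labels = np.zeros(dims, dtype=np.int16)
    labels[brain] = 1  # cortex = brain remainder
    region_names = {1: "cortex"}
    next_label = 2
    for name, ((cx, cy, cz), (rx, ry, rz)) in _REGION_GEOMETRY.items():
        for side, sign in (("_r", 1.0), ("_l", -1.0)):
            mask = (((u[0] - sign * cx) / rx) ** 2
                    + ((u[1] - cy) / ry) ** 2
                    + ((u[2] - cz) / rz) ** 2) <= 1.0
            mask &= brain
            if not mask.any():
                raise AtlasSizingError(
                    f"region {name + side!r} does not fit at dims {dims}")
            if np.any(labels[mask] > 1):
                raise AtlasSizingError(
                    f"region {name + side!r} overlaps a previous region "
                    f"at dims {dims}")
            labels[mask] = next_label
            region_names[next_label] = name + side
            next_label += 1
    return AtlasVolume(labels=labels, region_names=region_names,
                       voxel_size=voxel_size)


def make_phantom(atlas: AtlasVolume, label: str,
                 effect_map: dict[str, float] | None = None,
                 rng: np.random.Generator | None = None,
                 subject_sd: float = 0.05) -> Volume:
    """Draw one clean phantom for a subject of the given class.

    Each region's intensity is its baseline mean times a per-subject
    log-normal factor (sd ``subject_sd``); for ``label='ad'`` every region in
    ``effect_map`` is further multiplied by ``1 - effect_map[region]``.
    Background is zero.
    """
    if label not in ("control", "ad"):
        raise ValueError(f"label must be 'control' or 'ad', got {label!r}")
    if effect_map is None:
        effect_map = {}
    if rng is None:
        rng = np.random.default_rng()
    # validate effect regions and resolve base names to lateralized labels
    effect_by_label: dict[int, float] = {}
    for name, eff in effect_map.items():
        for lab in atlas.labels_for(name):
            effect_by_label[lab] = eff

    data = np.zeros(atlas.dims, dtype=np.float64)
    for lab in sorted(atlas.region_names):
        name = atlas.region_names[lab]
        base = REGION_VALUES.get(name.removesuffix("_l").removesuffix("_r"), 1.0)
        value = base * np.exp(rng.normal(0.0, subject_sd))
        if label == "ad" and lab in effect_by_label:
            value *= 1.0 - effect_by_label[lab]
        data[atlas.labels == lab] = value
    return Volume(data=data, voxel_size=atlas.voxel_size)


def degrade(clean: Volume, profile: ScannerProfile,
            rng: np.random.Generator | None = None,
            noise_model: str = "gaussian",
            poisson_counts: float = 1e4) -> Volume:
    """Forward degradation model: per-slice blur, then noise, then slicing.

    Each axial slice is convolved with the 2-D Gaussian PSF of width
    ``blur_sigma``; additive zero-mean Gaussian noise with sd equal to
    ``noise_sd`` times the mean in-brain (nonzero) intensity is added (or
    Poisson counting noise under ``noise_model='poisson'``); negatives are
    clipped to zero; the axial extent is decimated to ``n_slices`` by
    nearest-slice selection.
    """
    if rng is None:
        rng = np.random.default_rng()
    g = clean.data.astype(np.float64).copy()
    if profile.blur_sigma > 0:
        psf = make_psf(profile.blur_sigma)
        for z in range(g.shape[2]):
            g[:, :, z] = blur_slice(g[:, :, z], psf)
    brain = clean.data > 0
    mean_int = float(clean.data[brain].mean()) if brain.any() else 0.0
    if noise_model == "poisson":
        if g.sum() > 0:
            scale = poisson_counts / g.sum()
            g = rng.poisson(g * scale).astype(np.float64) / scale
    elif profile.noise_sd > 0 and mean_int > 0:
        g = g + rng.normal(0.0, profile.noise_sd * mean_int, size=g.shape)
    g = np.clip(g, 0.0, None)
    nz = g.shape[2]
    if profile.n_slices > nz:
        raise ValueError(
            f"n_slices={profile.n_slices} exceeds axial dim {nz}")
    if profile.n_slices != nz:
        idx = np.round(np.linspace(0, nz - 1, profile.n_slices)).astype(int)
        g = g[:, :, idx]
    return Volume(data=g, voxel_size=clean.voxel_size)


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write a full cohort (volumes + atlas + TSV manifest) to ``out_dir``.

    Returns the manifest as a DataFrame with columns
    ``id, label, volume, scanner``; the same table is written to
    ``manifest.tsv`` with volume paths relative to ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    atlas = build_atlas(spec.dims)
    atlas.to_nifti(out_dir / "atlas.nii.gz", out_dir / "atlas_labels.tsv")

    rng = np.random.default_rng(spec.seed)
    profiles = [p for p, _ in spec.scanner_profiles]
    weights = np.array([w for _, w in spec.scanner_profiles], dtype=float)
    weights /= weights.sum()

    records: list[SubjectRecord] = []
    labels = ["control"] * spec.n_control + ["ad"] * spec.n_ad
    for i, label in enumerate(labels):
        sid = f"sub-{i:04d}"
        profile = profiles[rng.choice(len(profiles), p=weights)]
        clean = make_phantom(atlas, label, spec.effect_map, rng,
                             subject_sd=spec.subject_sd)
        vol = degrade(clean, profile, rng, noise_model=spec.noise_model,
                      poisson_counts=spec.poisson_counts)
        rel = f"{sid}.nii.gz"
        vol.to_nifti(out_dir / rel)
        records.append(SubjectRecord(sid, label, rel, profile.name))

    manifest = pd.DataFrame([r.__dict__ for r in records]).rename(
        columns={"volume_path": "volume"})
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
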