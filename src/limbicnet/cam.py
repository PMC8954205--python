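"""Class activation maps and their anatomical summaries.

The network ends in global average pooling followed by two fully connected
layers, so vanilla CAM (one FC layer) does not apply directly.  The default
``method='cam'`` collapses FC-128 -> FC-2 into an effective per-channel
linear weight by multiplying the two weight matrices (ignoring the
intermediate ReLU); ``method='gradcam'`` instead weights each final-conv
channel by the spatial mean of the class-score gradient.  Either way the
weighted channel sum is trilinearly upsampled to the network input grid.

Maps computed on cropped inputs carry their :class:`~limbicnet.cropping.CropBox`
and are embedded back at the crop offset (zero elsewhere) before regional
summaries, so importance is always reported in whole-volume coordinates.
Only positive weights count toward importance (evidence *for* the AD class);
``non_brain_fraction`` is the share of total positive weight falling outside
the brain mask — the quantitative form of "the model attends to non-brain
regions".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .cropping import CropBox, embed
from .nn.network import ResNet3D, TrainedModel
from .volume import AtlasVolume

__all__ = ["ActivationMap", "RegionImportance", "cam", "average_maps",
           "region_importance"]

AD_CLASS = 1


@dataclass
class ActivationMap:
    """Per-voxel importance grid aligned to the network input grid."""

    weights: np.ndarray
    class_index: int = AD_CLASS
    crop_box: CropBox | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 3:
            raise ValueError("activation map must be 3-D")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("activation map contains non-finite values")


@dataclass
class RegionImportance:
    """Mean positive CAM weight per region, plus the non-brain share."""

    mean_weight: dict[str, float] = field(default_factory=dict)
    non_brain_fraction: float = 0.0
    ranking: list[str] = field(default_factory=list)


def _upsample(grid: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    if grid.shape == tuple(shape):
        return grid.astype(np.float64)
    return resize(grid.astype(np.float64), shape, order=1, mode="edge",
                  preserve_range=True, anti_aliasing=False)


def cam(model: TrainedModel | ResNet3D, volume: np.ndarray,
        class_index: int = AD_CLASS, method: str = "cam",
        crop_box: CropBox | None = None) -> ActivationMap:
    """Activation map for one subject volume (network input grid).

    ``volume`` is a 3-D array matching the model's input shape (channel axis
    added internally).
    """
    net = model.model if isinstance(model, TrainedModel) else model
    if method not in ("cam", "gradcam"):
        raise ValueError(f"unknown CAM method {method!r}")
    x = np.asarray(volume, dtype=np.float32)
    if x.ndim != 3:
        raise ValueError("volume must be a 3-D array")
    batch = x[None, None]
    logits = net.forward(batch, train=False)
    feats = net._features[0]  # (C, d, h, w)

    if method == "cam":
        w_eff = (net.fc2.W @ net.fc1.W)[class_index]  # (C,)
    else:
        donehot = np.zeros_like(logits)
        donehot[0, class_index] = 1.0
        # capture d(score)/d(features) at the res2 output
        dz = net.fc1.backward(net.fc_relu.backward(net.fc2.backward(donehot)))
        dfeat = net.gap.backward(dz)
        dfeat = net.res2_relu.backward(dfeat)
        # gradient arrives pre-ReLU; weight by spatial mean of the
        # post-skip gradient routed through the ReLU mask
        w_eff = dfeat[0].mean(axis=(1, 2, 3)) * np.prod(feats.shape[1:])
    grid = np.tensordot(w_eff.astype(np.float64), feats.astype(np.float64),
                        axes=([0], [0]))
    return ActivationMap(weights=_upsample(grid, x.shape),
                         class_index=class_index, crop_box=crop_box)


def average_maps(maps: list[ActivationMap]) -> ActivationMap:
    """Voxel-wise arithmetic mean of maps with identical dims and crop boxes."""
    if not maps:
        raise ValueError("no maps to average")
    first = maps[0]
    for m in maps[1:]:
        if m.weights.shape != first.weights.shape:
            raise ValueError("maps have mixed dims")
        if m.crop_box != first.crop_box:
            raise ValueError("maps have mixed crop boxes")
        if m.class_index != first.class_index:
            raise ValueError("maps target different classes")
    stack = np.stack([m.weights for m in maps])
    return ActivationMap(weights=stack.mean(axis=0),
                         class_index=first.class_index,
                         crop_box=first.crop_box)


def to_whole_grid(map_: ActivationMap, dims: tuple[int, int, int]) -> np.ndarray:
    """Map weights back to whole-volume coordinates through the crop offset."""
    w = map_.weights
    if map_.crop_box is None:
        return _upsample(w, dims)
    box = map_.crop_box
    if w.shape != box.shape:
        w = _upsample(w, box.shape)
    return embed(w, box, dims)


def region_importance(map_: ActivationMap, atlas: AtlasVolume,
                      brain_mask: np.ndarray | None = None) -> RegionImportance:
    """Per-region mean positive weight and the non-brain positive share."""
    if brain_mask is None:
        brain_mask = atlas.brain_mask
    whole = to_whole_grid(map_, atlas.dims)
    pos = np.clip(whole, 0.0, None)
    total = float(pos.sum())
    nbf = float(pos[~brain_mask].sum() / total) if total > 0 else 0.0
    means: dict[str, float] = {}
    for lab in sorted(atlas.region_names):
        name = atlas.region_names[lab]
        region = atlas.labels == lab
        n = int(region.sum())
        if n == 0:
            continue  # absent region: reported as absent, not an error
        means[name] = float(pos[region].mean())
    ranking = sorted((n for n in means if means[n] > 0),
                     key=lambda n: (-means[n], n))
    return RegionImportance(mean_weight=means, non_brain_fraction=nbf,
                            ranking=ranking)
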