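"""The 3-D residual CNN classifier and its training recipe.

Architecture (channels configurable; defaults follow the reference design):
7x7x7 stride-2 conv -> BN -> ReLU -> 3x3x3 stride-2 max-pool -> residual
stage 1 (3x3x3 conv + BN with identity skip) -> residual stage 2 (3x3x3
stride-2 conv + BN with a 1x1x1 stride-2 conv+BN projection branch) ->
global average pooling -> FC-128 -> ReLU -> FC-2 -> softmax.

Training uses mini-batch cross-entropy with the Adam optimizer (defaults:
batch size 4, 20 epochs, learning rate 1e-4) and records the mean training
loss and the test loss per epoch.  Everything is seeded NumPy, so identical
configurations give bit-identical weights and loss curves on CPU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .layers import (Adam, BatchNorm3d, Conv3d, GlobalAvgPool, Linear,
                     MaxPool3d, ReLU, SoftmaxCrossEntropy, softmax)

__all__ = [
    "ModelConfig", "ConfigError", "TrainedModel", "ResNet3D",
    "layer_shapes", "build_model", "train", "predict",
    "save_model", "load_model",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Network and training hyperparameters."""

    input_shape: tuple[int, int, int] = (128, 128, 79)
    in_channels: int = 1
    base_channels: int = 64
    stage_channels: tuple[int, int] = (64, 128)
    fc_hidden: int = 128
    lr: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 4
    epochs: int = 20
    seed: int = 0
    loss: str = "cross_entropy"
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.loss != "cross_entropy":
            raise ConfigError(f"unsupported loss {self.loss!r}")
        if self.optimizer != "adam":
            raise ConfigError(f"unsupported optimizer {self.optimizer!r}")
        if self.lr < 0 or self.batch_size < 1 or self.epochs < 1:
            raise ConfigError("invalid training hyperparameters")


def _conv_dim(d: int, k: int, s: int, p: int) -> int:
    return (d + 2 * p - k) // s + 1


def layer_shapes(cfg: ModelConfig) -> list[tuple[str, tuple[int, ...]]]:
    """Symbolic shape trace ``(layer name, (x, y, z, channels))`` per layer.

    Raises :class:`ConfigError` naming the first layer whose output would
    have a non-positive spatial dim.
    """
    x, y, z = cfg.input_shape
    if min(x, y, z) < 1:
        raise ConfigError(f"layer 'input' has non-positive dims {(x, y, z)}")
    trace: list[tuple[str, tuple[int, ...]]] = [("input", (x, y, z, cfg.in_channels))]

    def step(name: str, k: int, s: int, p: int, c: int) -> None:
        nonlocal x, y, z
        x, y, z = (_conv_dim(x, k, s, p), _conv_dim(y, k, s, p),
                   _conv_dim(z, k, s, p))
        if min(x, y, z) < 1:
            raise ConfigError(f"layer {name!r} produces non-positive dims "
                              f"({x}, {y}, {z})")
        trace.append((name, (x, y, z, c)))

    c0, (c1, c2) = cfg.base_channels, cfg.stage_channels
    step("conv1", 7, 2, 3, c0)
    trace.append(("bn1", (x, y, z, c0)))
    trace.append(("relu1", (x, y, z, c0)))
    step("maxpool", 3, 2, 1, c0)
    step("res1_conv", 3, 1, 1, c1)
    trace.append(("res1_bn", (x, y, z, c1)))
    trace.append(("res1_relu", (x, y, z, c1)))
    step("res2_conv", 3, 2, 1, c2)
    trace.append(("res2_bn", (x, y, z, c2)))
    trace.append(("res2_relu", (x, y, z, c2)))
    trace.append(("gap", (1, 1, 1, c2)))
    trace.append(("fc1", (1, 1, 1, cfg.fc_hidden)))
    trace.append(("fc2", (1, 1, 1, 2)))
    trace.append(("softmax", (1, 1, 1, 2)))
    return trace


class ResNet3D:
    """NumPy implementation of the residual 3-D classifier."""

    def __init__(self, cfg: ModelConfig):
        if cfg.base_channels != cfg.stage_channels[0]:
            raise ConfigError("stage 1 uses an identity skip, so "
                              "stage_channels[0] must equal base_channels")
        layer_shapes(cfg)  # validates spatial dims
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c0, (c1, c2) = cfg.base_channels, cfg.stage_channels
        self.conv1 = Conv3d(cfg.in_channels, c0, 7, 2, 3, rng)
        self.bn1 = BatchNorm3d(c0)
        self.relu1 = ReLU()
        self.pool = MaxPool3d(3, 2, 1)
        self.res1_conv = Conv3d(c0, c1, 3, 1, 1, rng)
        self.res1_bn = BatchNorm3d(c1)
        self.res1_relu = ReLU()
        self.res2_conv = Conv3d(c1, c2, 3, 2, 1, rng)
        self.res2_bn = BatchNorm3d(c2)
        self.res2_branch_conv = Conv3d(c1, c2, 1, 2, 0, rng)
        self.res2_branch_bn = BatchNorm3d(c2)
        self.res2_relu = ReLU()
        self.gap = GlobalAvgPool()
        self.fc1 = Linear(c2, cfg.fc_hidden, rng)
        self.fc_relu = ReLU()
        self.fc2 = Linear(cfg.fc_hidden, 2, rng)
        self._features: np.ndarray | None = None

    def _layers(self):
        return [self.conv1, self.bn1, self.relu1, self.pool,
                self.res1_conv, self.res1_bn, self.res1_relu,
                self.res2_conv, self.res2_bn,
                self.res2_branch_conv, self.res2_branch_bn, self.res2_relu,
                self.gap, self.fc1, self.fc_relu, self.fc2]

    def params(self) -> list[np.ndarray]:
        return [p for lyr in self._layers() for p in lyr.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for lyr in self._layers() for g in lyr.grads()]

    def buffers(self) -> list[np.ndarray]:
        out = []
        for lyr in self._layers():
            if isinstance(lyr, BatchNorm3d):
                out += [lyr.running_mean, lyr.running_var]
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train),
                                                train), train)
        h = self.pool.forward(h, train)
        r = self.res1_bn.forward(self.res1_conv.forward(h, train), train)
        h1 = self.res1_relu.forward(r + h, train)
        r2 = self.res2_bn.forward(self.res2_conv.forward(h1, train), train)
        s2 = self.res2_branch_bn.forward(
            self.res2_branch_conv.forward(h1, train), train)
        h2 = self.res2_relu.forward(r2 + s2, train)
        self._features = h2
        z = self.gap.forward(h2, train)
        a = self.fc_relu.forward(self.fc1.forward(z, train), train)
        return self.fc2.forward(a, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc1.backward(self.fc_relu.backward(self.fc2.backward(dlogits)))
        d = self.gap.backward(d)
        d = self.res2_relu.backward(d)
        d_main = self.res2_conv.backward(self.res2_bn.backward(d))
        d_branch = self.res2_branch_conv.backward(self.res2_branch_bn.backward(d))
        d = d_main + d_branch
        d = self.res1_relu.backward(d)
        d = self.res1_conv.backward(self.res1_bn.backward(d)) + d
        d = self.pool.backward(d)
        self.conv1.backward(self.bn1.backward(self.relu1.backward(d)),
                            need_dx=False)

    def recalibrate_bn(self, x: np.ndarray, batch_size: int = 8) -> None:
        """Replace BN running statistics with exact population statistics
        computed in one pass over ``x`` (batch-normalized activations vary
        too much at batch size 4 for the exponential running estimate to
        match them at test time)."""
        bns = [lyr for lyr in self._layers() if isinstance(lyr, BatchNorm3d)]
        for bn in bns:
            bn.start_accumulate()
        for i in range(0, len(x), batch_size):
            self.forward(x[i:i + batch_size], train=True)
        for bn in bns:
            bn.finish_accumulate()

    def predict_proba(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i:i + batch_size], train=False)
            out.append(softmax(logits.astype(np.float64)))
        return np.concatenate(out, axis=0)

    def shape_trace(self, batch: np.ndarray) -> list[tuple[str, tuple[int, ...]]]:
        """Actual per-layer output shapes of a forward pass, for
        cross-checking against :func:`layer_shapes`."""
        names = ["conv1", "bn1", "relu1", "maxpool", "res1_conv", "res1_bn",
                 "res1_relu", "res2_conv", "res2_bn", "res2_relu", "gap",
                 "fc1", "fc2"]
        trace: list[tuple[str, tuple[int, ...]]] = []
        x = batch

        def rec(name, arr):
            if arr.ndim == 5:
                n, c, d, h, w = arr.shape
                trace.append((name, (d, h, w, c)))
            else:
                trace.append((name, (1, 1, 1, arr.shape[1])))

        h = self.conv1.forward(x, False); rec("conv1", h)
        h = self.bn1.forward(h, False); rec("bn1", h)
        h = self.relu1.forward(h, False); rec("relu1", h)
        h = self.pool.forward(h, False); rec("maxpool", h)
        r = self.res1_conv.forward(h, False); rec("res1_conv", r)
        r = self.res1_bn.forward(r, False); rec("res1_bn", r)
        h1 = self.res1_relu.forward(r + h, False); rec("res1_relu", h1)
        r2 = self.res2_conv.forward(h1, False); rec("res2_conv", r2)
        r2 = self.res2_bn.forward(r2, False); rec("res2_bn", r2)
        s2 = self.res2_branch_bn.forward(
            self.res2_branch_conv.forward(h1, False), False)
        h2 = self.res2_relu.forward(r2 + s2, False); rec("res2_relu", h2)
        z = self.gap.forward(h2, False); rec("gap", z)
        a = self.fc_relu.forward(self.fc1.forward(z, False), False)
        rec("fc1", a)
        logits = self.fc2.forward(a, False); rec("fc2", logits)
        assert [n for n, _ in trace] == names
        return trace


@dataclass
class TrainedModel:
    """A fitted network with its per-epoch loss curves."""

    model: ResNet3D
    train_loss_curve: list[float] = field(default_factory=list)
    test_loss_curve: list[float] = field(default_factory=list)

    @property
    def config(self) -> ModelConfig:
        return self.model.cfg


def build_model(cfg: ModelConfig) -> ResNet3D:
    """Construct the network with seed-controlled initial weights."""
    return ResNet3D(cfg)


def _check_dataset(x: np.ndarray, y: np.ndarray, cfg: ModelConfig, what: str):
    if len(x) == 0:
        raise ValueError(f"{what} set is empty")
    if x.shape[1:] != (cfg.in_channels, *cfg.input_shape):
        raise ValueError(f"{what} volumes have shape {x.shape[1:]}, expected "
                         f"{(cfg.in_channels, *cfg.input_shape)}")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError(f"{what} labels must be binary 0/1")


def train(model: ResNet3D, train_set: tuple[np.ndarray, np.ndarray],
          test_set: tuple[np.ndarray, np.ndarray],
          cfg: ModelConfig | None = None) -> TrainedModel:
    """Run the full training loop and record loss curves.

    Exactly ``cfg.epochs`` epochs of shuffled mini-batch Adam updates on the
    cross-entropy loss; the shuffling stream is seeded, so repeated runs are
    identical.  Raises if the training set contains a single class.
    """
    if cfg is None:
        cfg = model.cfg
    x_tr, y_tr = train_set
    x_te, y_te = test_set
    x_tr = np.ascontiguousarray(x_tr, dtype=np.float32)
    x_te = np.ascontiguousarray(x_te, dtype=np.float32)
    y_tr = np.asarray(y_tr, dtype=np.int64)
    y_te = np.asarray(y_te, dtype=np.int64)
    _check_dataset(x_tr, y_tr, cfg, "training")
    _check_dataset(x_te, y_te, cfg, "test")
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training set contains a single class; "
                         "cross-entropy training is degenerate")

    loss_fn = SoftmaxCrossEntropy()
    opt = Adam(model.params(), model.grads(), lr=cfg.lr,
               weight_decay=cfg.weight_decay)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 81]))
    trained = TrainedModel(model=model)
    for epoch in range(cfg.epochs):
        perm = shuffle_rng.permutation(len(x_tr))
        total, count = 0.0, 0
        for i in range(0, len(perm), cfg.batch_size):
            sel = perm[i:i + cfg.batch_size]
            logits = model.forward(x_tr[sel], train=True)
            loss = loss_fn.forward(logits, y_tr[sel])
            model.backward(loss_fn.backward())
            if cfg.lr > 0:
                opt.step()
            total += loss * len(sel)
            count += len(sel)
        trained.train_loss_curve.append(total / count)

        if epoch == cfg.epochs - 1:
            # exact population BN statistics for the final (deployed) model;
            # intermediate epochs keep the cheap exponential estimate
            model.recalibrate_bn(x_tr, batch_size=max(cfg.batch_size, 16))
        te_total = 0.0
        for i in range(0, len(x_te), cfg.batch_size):
            logits = model.forward(x_te[i:i + cfg.batch_size], train=False)
            te_total += loss_fn.forward(logits, y_te[i:i + cfg.batch_size]) \
                * len(x_te[i:i + cfg.batch_size])
        trained.test_loss_curve.append(te_total / len(x_te))
    return trained


def predict(trained: TrainedModel | ResNet3D, volumes: np.ndarray,
            batch_size: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and hard labels (ties break toward control=0)."""
    model = trained.model if isinstance(trained, TrainedModel) else trained
    x = np.ascontiguousarray(volumes, dtype=np.float32)
    if x.shape[1:] != (model.cfg.in_channels, *model.cfg.input_shape):
        raise ValueError(f"volumes have shape {x.shape[1:]}, expected "
                         f"{(model.cfg.in_channels, *model.cfg.input_shape)}")
    probs = model.predict_proba(x, batch_size=batch_size)
    labels = (probs[:, 1] > probs[:, 0]).astype(np.int64)
    return probs, labels


def save_model(trained: TrainedModel, path_prefix: str | Path) -> None:
    """Write weights (npz) plus a JSON config/shape manifest."""
    prefix = Path(path_prefix)
    model = trained.model
    arrays = {f"p{i}": p for i, p in enumerate(model.params())}
    arrays.update({f"b{i}": b for i, b in enumerate(model.buffers())})
    np.savez(str(prefix) + ".npz", **arrays)
    manifest = {
        "config": asdict(model.cfg),
        "layer_shapes": [[n, list(s)] for n, s in layer_shapes(model.cfg)],
        "train_loss_curve": trained.train_loss_curve,
        "test_loss_curve": trained.test_loss_curve,
    }
    with open(str(prefix) + ".json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_model(path_prefix: str | Path) -> TrainedModel:
    prefix = Path(path_prefix)
    with open(str(prefix) + ".json") as fh:
        manifest = json.load(fh)
    c = manifest["config"]
    for key in ("input_shape", "stage_channels"):
        c[key] = tuple(c[key])
    model = ResNet3D(ModelConfig(**c))
    data = np.load(str(prefix) + ".npz")
    for i, p in enumerate(model.params()):
        p[...] = data[f"p{i}"]
    for i, b in enumerate(model.buffers()):
        b[...] = data[f"b{i}"]
    return TrainedModel(model=model,
                        train_loss_curve=manifest["train_loss_curve"],
                        test_loss_curve=manifest["test_loss_curve"])
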