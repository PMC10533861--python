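"""Residual patch-scoring network: architecture, training, inference.

The default architecture mirrors the deployed detector's census — 39
convolutional layers (1 stem, 18 two-convolution basic blocks, 2
projection shortcuts at the width transitions), one global average
pooling layer, one fully connected layer — applied to 5x24x24 patch
stacks whose five slices enter as image channels, with a sigmoid output
in [0, 1].  Channel widths are desk-scale (8/16/32 by default) because
the network here demonstrates the pipeline contract, not clinical
accuracy.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np

from ..extraction import PATCH_SHAPE, PatchStack
from .layers import DTYPE, BatchNorm2D, Conv2D, Dense, GlobalAvgPool2D, Parameter, ReLU
from .nadam import Nadam

__all__ = [
    "ArchitectureSpec",
    "TrainingConfig",
    "DESK_PROFILE",
    "FULL_PROFILE",
    "ResNetScorer",
    "build_model",
    "train",
    "score_patches",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ArchitectureSpec:
    """Declarative architecture description with a machine-checkable census."""

    n_conv_layers: int = 39
    has_average_pooling: bool = True
    n_fully_connected: int = 1
    input_shape: tuple[int, int, int] = PATCH_SHAPE
    activation: str = "relu"
    uses_batch_norm: bool = True
    uses_skip_connections: bool = True
    base_width: int = 8  # channels of the first stage; doubles per stage

    def __post_init__(self) -> None:
        if self.activation != "relu":
            raise ValueError("only rectified-linear activation is supported")
        if self.n_fully_connected != 1:
            raise ValueError("the classifier head is a single fully connected layer")
        if not self.has_average_pooling:
            raise ValueError("the head requires the average pooling layer")
        if tuple(self.input_shape) != PATCH_SHAPE:
            raise ValueError(f"input_shape must be {PATCH_SHAPE}")
        n_proj = 2 if self.uses_skip_connections else 0
        body = self.n_conv_layers - 1 - n_proj
        # at least one block per stage so both width transitions (and hence
        # both projection shortcuts) exist and the census is exact
        if body < 6 or body % 2 != 0:
            raise ValueError(
                f"n_conv_layers={self.n_conv_layers} does not decompose into a stem, "
                f"{n_proj} projection shortcuts and >= 3 two-convolution blocks"
            )
        if self.base_width < 1:
            raise ValueError("base_width must be >= 1")

    @property
    def n_blocks(self) -> int:
        n_proj = 2 if self.uses_skip_connections else 0
        return (self.n_conv_layers - 1 - n_proj) // 2

    @property
    def stage_sizes(self) -> tuple[int, int, int]:
        n = self.n_blocks
        base, extra = divmod(n, 3)
        return tuple(base + (1 if i < extra else 0) for i in range(3))


@dataclass
class TrainingConfig:
    """Optimizer and schedule settings.

    The optimizer quintuple defaults to the study's printed values
    (Nadam: learning rate 0.002, beta_1 0.9, beta_2 0.999, epsilon 1e-8,
    schedule decay 0.004).
    """

    learning_rate: float = 0.002
    beta_1: float = 0.9
    beta_2: float = 0.999
    epsilon: float = 1e-8
    schedule_decay: float = 0.004
    epochs: int = 20
    batch_size: int = 32
    seed: int = 0
    validation_fraction: float = 0.2

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.beta_1, self.beta_2, self.epsilon,
               self.schedule_decay) <= 0:
            raise ValueError("all optimizer rates must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")


#: fast profile for pipeline demonstrations and tests
DESK_PROFILE = TrainingConfig(epochs=20, batch_size=32)
#: the deployed detector's original 100-epoch schedule
FULL_PROFILE = TrainingConfig(epochs=100, batch_size=32)


class _BasicBlock:
    """conv-bn-relu-conv-bn (+ shortcut, optionally 1x1 conv projection) -> relu."""

    def __init__(self, c_in: int, c_out: int, stride: int, project: bool,
                 rng: np.random.Generator, name: str):
        self.conv1 = Conv2D(c_in, c_out, 3, stride, rng, f"{name}.conv1")
        self.bn1 = BatchNorm2D(c_out, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv2D(c_out, c_out, 3, 1, rng, f"{name}.conv2")
        self.bn2 = BatchNorm2D(c_out, name=f"{name}.bn2")
        self.relu2 = ReLU()
        self.proj = self.proj_bn = None
        if project:
            self.proj = Conv2D(c_in, c_out, 1, stride, rng, f"{name}.proj")
            self.proj_bn = BatchNorm2D(c_out, name=f"{name}.proj_bn")
        self.params: list[Parameter] = []
        for layer in (self.conv1, self.bn1, self.conv2, self.bn2, self.proj, self.proj_bn):
            if layer is not None:
                self.params.extend(layer.params)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        shortcut = x
        if self.proj is not None:
            shortcut = self.proj_bn.forward(self.proj.forward(x, train), train)
        return self.relu2.forward(out + shortcut, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.relu2.backward(grad)
        g_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(grad)))))
        if self.proj is not None:
            g_short = self.proj.backward(self.proj_bn.backward(grad))
        else:
            g_short = grad
        return g_main + g_short


class _PlainBlock:
    """Two conv-bn-relu pairs without a shortcut (ablation configuration)."""

    def __init__(self, c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator, name: str):
        self.layers = [
            Conv2D(c_in, c_out, 3, stride, rng, f"{name}.conv1"),
            BatchNorm2D(c_out, name=f"{name}.bn1"),
            ReLU(),
            Conv2D(c_out, c_out, 3, 1, rng, f"{name}.conv2"),
            BatchNorm2D(c_out, name=f"{name}.bn2"),
            ReLU(),
        ]
        self.params = [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class ResNetScorer:
    """The trainable Scorer implementation (numpy forward/backward)."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        c_in = spec.input_shape[0]
        widths = [spec.base_width * (2 ** i) for i in range(3)]

        self.stem_conv = Conv2D(c_in, widths[0], 3, 1, rng, "stem.conv")
        self.stem_bn = BatchNorm2D(widths[0], name="stem.bn")
        self.stem_relu = ReLU()
        self.blocks: list = []
        prev = widths[0]
        for stage, (width, n_blocks) in enumerate(zip(widths, spec.stage_sizes)):
            for b in range(n_blocks):
                stride = 2 if (stage > 0 and b == 0) else 1
                name = f"stage{stage}.block{b}"
                if spec.uses_skip_connections:
                    project = prev != width or stride != 1
                    self.blocks.append(_BasicBlock(prev, width, stride, project, rng, name))
                else:
                    self.blocks.append(_PlainBlock(prev, width, stride, rng, name))
                prev = width
        self.pool = GlobalAvgPool2D()
        self.fc = Dense(prev, 1, rng, "fc")

        self.params: list[Parameter] = list(self.stem_conv.params) + list(self.stem_bn.params)
        for block in self.blocks:
            self.params.extend(block.params)
        self.params.extend(self.fc.params)
        self.history: dict = {}
        self.metadata = {
            "architecture": "residual-cnn",
            "census": self.layer_census(),
            "seed": seed,
        }

    def layer_census(self) -> dict[str, int]:
        """Count layers by type; the contract the architecture must meet."""
        n_conv = 1  # stem
        n_bn = 1
        for block in self.blocks:
            if isinstance(block, _BasicBlock):
                n_conv += 2 + (1 if block.proj is not None else 0)
                n_bn += 2 + (1 if block.proj_bn is not None else 0)
            else:
                n_conv += 2
                n_bn += 2
        return {
            "convolutional": n_conv,
            "average_pooling": 1,
            "fully_connected": 1,
            "batch_norm": n_bn,
        }

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1:] != self.spec.input_shape:
            raise ValueError(
                f"expected input (N, {self.spec.input_shape}), got {x.shape}"
            )
        out = self.stem_relu.forward(
            self.stem_bn.forward(self.stem_conv.forward(x, train), train), train
        )
        for block in self.blocks:
            out = block.forward(out, train)
        return self.fc.forward(self.pool.forward(out, train), train)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        grad = self.pool.backward(self.fc.backward(dlogits[:, None].astype(DTYPE)))
        for block in reversed(self.blocks):
            grad = block.backward(grad)
        self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(grad)))

    def score_patches(self, patches) -> np.ndarray:
        """Inference: sigmoid scores in [0, 1]; no state is mutated."""
        x = _to_array(patches, self.spec.input_shape)
        if x.shape[0] == 0:
            return np.empty(0)
        logits = self.forward_logits(x, train=False).astype(np.float64)
        return 1.0 / (1.0 + np.exp(-logits))

    def parameter_checksum(self) -> int:
        blob = b"".join(np.ascontiguousarray(p.value).tobytes() for p in self.params)
        return zlib.crc32(blob)


def _to_array(patches, input_shape) -> np.ndarray:
    if isinstance(patches, np.ndarray):
        arr = patches.astype(DTYPE)
    else:
        arr = np.array([
            p.values if isinstance(p, PatchStack) else np.asarray(p) for p in patches
        ], dtype=DTYPE)
    if arr.size == 0:
        return np.empty((0, *input_shape))
    if arr.ndim != 4 or arr.shape[1:] != tuple(input_shape):
        raise ValueError(f"patches must have shape (N, {input_shape}), got {arr.shape}")
    return arr


def build_model(spec: ArchitectureSpec | None = None, seed: int = 0) -> ResNetScorer:
    """Construct the scorer; identical spec and seed give bit-identical
    initial parameters."""
    return ResNetScorer(spec or ArchitectureSpec(), seed)


def _bce_loss_and_grad(logits: np.ndarray, y: np.ndarray):
    # numerically stable sigmoid cross-entropy
    logits = logits.astype(np.float64)
    loss = np.mean(np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits))))
    p = 1.0 / (1.0 + np.exp(-logits))
    return float(loss), (p - y) / len(y)


def train(scorer: ResNetScorer, patches, labels, config: TrainingConfig | None = None) -> ResNetScorer:
    """Train in place with Nadam on binary cross-entropy; returns the scorer.

    Uses a seeded stratified train/validation split (80/20 by default) and
    records per-epoch training and validation losses in ``scorer.history``.
    Refuses single-class data.
    """
    config = config or DESK_PROFILE
    x = _to_array(patches, scorer.spec.input_shape)
    y = np.asarray(labels, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError("patches and labels must have equal length")
    if len(y) < 2:
        raise ValueError("need at least 2 training examples")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes to be present")

    rng = np.random.default_rng(config.seed)
    # stratified split
    train_idx, val_idx = [], []
    for cls in (0.0, 1.0):
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        n_val = int(round(config.validation_fraction * len(idx)))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)

    optimizer = Nadam(
        scorer.params,
        config.learning_rate,
        config.beta_1,
        config.beta_2,
        config.epsilon,
        config.schedule_decay,
    )
    train_losses, val_losses = [], []
    for _epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        batch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            optimizer.zero_grad()
            logits = scorer.forward_logits(x[batch], train=True)
            loss, dlogits = _bce_loss_and_grad(logits, y[batch])
            scorer.backward(dlogits)
            optimizer.step()
            batch_losses.append(loss)
        train_losses.append(float(np.mean(batch_losses)))
        if len(val_idx):
            val_logits = scorer.forward_logits(x[val_idx], train=False)
            val_losses.append(_bce_loss_and_grad(val_logits, y[val_idx])[0])
    scorer.history = {"train_loss": train_losses, "val_loss": val_losses}
    return scorer


def score_patches(scorer, patches) -> np.ndarray:
    """Score patches with any Scorer (network or rule-based)."""
    return scorer.score_patches(patches)


def save_checkpoint(scorer: ResNetScorer, weights_path, metadata_path) -> None:
    """Write weights (npz) plus a JSON sidecar with census, seed and history."""
    arrays = {f"param_{i}": p.value for i, p in enumerate(scorer.params)}
    bn_stats = {}
    idx = 0
    for layer in _iter_bn_layers(scorer):
        bn_stats[f"bn{idx}_mean"] = layer.running_mean
        bn_stats[f"bn{idx}_var"] = layer.running_var
        idx += 1
    np.savez(weights_path, **arrays, **bn_stats)
    with open(metadata_path, "w") as fh:
        json.dump(
            {
                "census": scorer.layer_census(),
                "seed": scorer.seed,
                "base_width": scorer.spec.base_width,
                "n_conv_layers": scorer.spec.n_conv_layers,
                "uses_skip_connections": scorer.spec.uses_skip_connections,
                "history": scorer.history,
            },
            fh,
            indent=2,
        )


def _iter_bn_layers(scorer: ResNetScorer):
    yield scorer.stem_bn
    for block in scorer.blocks:
        if isinstance(block, _BasicBlock):
            yield block.bn1
            yield block.bn2
            if block.proj_bn is not None:
                yield block.proj_bn
        else:
            for layer in block.layers:
                if isinstance(layer, BatchNorm2D):
                    yield layer


def load_checkpoint(weights_path, metadata_path) -> ResNetScorer:
    with open(metadata_path) as fh:
        meta = json.load(fh)
    spec = ArchitectureSpec(
        n_conv_layers=meta["n_conv_layers"],
        uses_skip_connections=meta["uses_skip_connections"],
        base_width=meta["base_width"],
    )
    scorer = ResNetScorer(spec, meta["seed"])
    data = np.load(weights_path)
    for i, p in enumerate(scorer.params):
        p.value[:] = data[f"param_{i}"]
    for idx, layer in enumerate(_iter_bn_layers(scorer)):
        layer.running_mean = data[f"bn{idx}_mean"]
        layer.running_var = data[f"bn{idx}_var"]
    scorer.history = meta.get("history", {})
    return scorer
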