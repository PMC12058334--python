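"""3D convolutional flow-state classifier: architecture, training, inference.

The network follows the conv–batchnorm–ReLU block pattern of efficient 3D
video classifiers (X3D-style): a stem convolution preserving the input
resolution, a stack of intermediate blocks whose channel count grows while
pooling halves the spatiotemporal dimensions, a global average pool and a
dense softmax head over the four flow states.  Training uses mini-batch Adam
on categorical cross-entropy with best-validation-accuracy checkpointing.

Two configuration profiles are provided: the full-scale profile mirroring
the phantom study (stem 24 filters, channel schedule 24→48→96→192 on
3x64x224x224 chunks) and a desk-scale profile (stem 8, schedule 8→16→32 on
3x64x64x64 chunks) that trains in minutes on a CPU.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .conditions import FlowCondition
from .preprocess import Chunk, DatasetSplit

__all__ = [
    "ModelConfig", "TrainConfig", "TrainHistory",
    "build_model", "train", "predict_chunks", "predict_labels", "vote_video",
    "cross_entropy", "save_checkpoint", "load_checkpoint",
]

cross_entropy = nn.cross_entropy


@dataclass(frozen=True)
class ModelConfig:
    """Architecture description of the classifier.

    ``block_channels`` is the output-channel schedule of the intermediate
    blocks following the stem; a 2x2x2 max pool follows the stem and each
    block.  ``head_hidden`` inserts an optional dense+ReLU layer before the
    softmax head.
    """

    stem_filters: int = 24
    stem_kernel: tuple[int, int, int] = (3, 3, 3)
    stem_stride: tuple[int, int, int] = (1, 1, 1)
    stem_padding: tuple[int, int, int] = (1, 1, 1)
    block_channels: tuple[int, ...] = (48, 96, 192)
    head_hidden: int | None = None
    n_classes: int = 4

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        schedule = (self.stem_filters, *self.block_channels)
        if any(b > a2 for b, a2 in zip(schedule, schedule[1:])):
            raise ValueError("channel schedule must be non-decreasing")

    @classmethod
    def desk_scale(cls, n_classes: int = 4) -> "ModelConfig":
        """Reduced profile trainable on one CPU in minutes."""
        return cls(stem_filters=8, block_channels=(16, 32), n_classes=n_classes)


@dataclass(frozen=True)
class TrainConfig:
    """Training recipe: Adam at 1e-3, batch size 8, 20 epochs."""

    batch_size: int = 8
    epochs: int = 20
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    half_precision: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainHistory:
    """Per-epoch training curves."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int | None = None

    def __len__(self):
        return len(self.train_loss)


def build_model(
    config: ModelConfig, input_shape: tuple[int, int, int, int], seed: int = 0
) -> nn.Sequential:
    """Assemble the network for inputs of shape (channels, T, H, W).

    Raises a shape error naming the offending stage if the pooling schedule
    would shrink any dimension below 1.
    """
    c, d, h, w = input_shape
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []

    def add_block(c_in, c_out, stage):
        nonlocal d, h, w
        layers.append(nn.Conv3d(c_in, c_out, kernel=3, rng=rng))
        layers.append(nn.BatchNorm3d(c_out))
        layers.append(nn.ReLU())
        if d % 2 or h % 2 or w % 2 or min(d, h, w) < 2:
            raise ValueError(
                f"input too small for pooling at stage {stage!r}: "
                f"dims {(d, h, w)} not divisible by 2"
            )
        layers.append(nn.MaxPool3d(2))
        d, h, w = d // 2, h // 2, w // 2

    add_block(c, config.stem_filters, "stem")
    layers[0].skip_input_grad = True  # no layer consumes the stem's input grad
    c_prev = config.stem_filters
    for i, c_out in enumerate(config.block_channels):
        add_block(c_prev, c_out, f"block{i + 1}")
        c_prev = c_out
    layers.append(nn.GlobalAvgPool3d())
    if config.head_hidden:
        layers.append(nn.Linear(c_prev, config.head_hidden, rng=rng))
        layers.append(nn.ReLU())
        c_prev = config.head_hidden
    layers.append(nn.Linear(c_prev, config.n_classes, rng=rng))
    model = nn.Sequential(layers)
    model.config = config
    model.input_shape = tuple(input_shape)
    return model


def _assemble_batch(chunks: list[Chunk], n_classes: int, dtype) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([c.to_tensor() for c in chunks]).astype(dtype)
    y = np.zeros((len(chunks), n_classes), dtype=np.float32)
    for i, c in enumerate(chunks):
        y[i, int(c.label)] = 1.0
    return x, y


def _evaluate(model: nn.Sequential, chunks: list[Chunk], n_classes: int,
              batch_size: int, dtype) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(chunks), batch_size):
        batch = chunks[i:i + batch_size]
        x, y = _assemble_batch(batch, n_classes, dtype)
        probs = nn.softmax(model.forward(x, training=False))
        losses.append(nn.cross_entropy(y, probs) * len(batch))
        correct += int((probs.argmax(axis=1) == y.argmax(axis=1)).sum())
    return sum(losses) / len(chunks), correct / len(chunks)


def train(
    model: nn.Sequential, split: DatasetSplit, cfg: TrainConfig
) -> tuple[nn.Sequential, TrainHistory]:
    """Train with mini-batch Adam on categorical cross-entropy.

    Records per-epoch curves and restores the parameters of the epoch with
    the best validation accuracy (ties resolved toward the later epoch).
    ``epochs=0`` returns the model unchanged with an empty history.
    """
    history = TrainHistory()
    if cfg.epochs == 0:
        return model, history
    if not split.train_chunks:
        raise ValueError("training split is empty")
    n_classes = model.config.n_classes
    present = {int(c.label) for c in split.train_chunks}
    missing = sorted(set(range(n_classes)) - present)
    if missing:
        names = [FlowCondition(m).name if m < len(FlowCondition) else str(m)
                 for m in missing]
        raise ValueError(f"classes absent from training data: {names}")

    dtype = np.float16 if cfg.half_precision else np.float32
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model, lr=cfg.learning_rate)
    val_chunks = split.val_chunks or split.train_chunks
    best_state, best_acc = None, -1.0

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(split.train_chunks))
        epoch_loss, correct = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            batch = [split.train_chunks[j] for j in order[i:i + cfg.batch_size]]
            x, y = _assemble_batch(batch, n_classes, dtype)
            logits = model.forward(x, training=True)
            probs = nn.softmax(logits)
            epoch_loss += nn.cross_entropy(y, probs) * len(batch)
            correct += int((probs.argmax(axis=1) == y.argmax(axis=1)).sum())
            # fused softmax+CE gradient w.r.t. logits, averaged over the batch
            model.backward(((probs - y) / len(batch)).astype(np.float32))
            opt.step()
        val_loss, val_acc = _evaluate(model, val_chunks, n_classes,
                                      cfg.batch_size, dtype)
        history.train_loss.append(epoch_loss / len(order))
        history.train_accuracy.append(correct / len(order))
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        if val_acc >= best_acc:  # ties -> later epoch
            best_acc = val_acc
            best_state = {k: v.copy() for k, v in model.named_params().items()}
            history.best_epoch = epoch

    if best_state is not None:
        for k, p in model.named_params().items():
            p[...] = best_state[k]
    _recalibrate_batchnorm(model, split.train_chunks, cfg.batch_size, dtype)
    return model, history


def _recalibrate_batchnorm(model: nn.Sequential, chunks: list[Chunk],
                           batch_size: int, dtype) -> None:
    """Re-estimate batch-norm running statistics with the final weights.

    During training the running averages trail the (moving) weights; on small
    datasets that gap degrades eval-mode accuracy.  A pass over the training
    chunks with momentum 1/i turns the running statistics into the exact
    average of the per-batch statistics under the frozen weights.
    """
    bns = [l for l in model.layers if isinstance(l, nn.BatchNorm3d)]
    if not bns or not chunks:
        return
    n_classes = model.config.n_classes
    for i, start in enumerate(range(0, len(chunks), batch_size), start=1):
        for bn in bns:
            bn.momentum = 1.0 / i
        x, _ = _assemble_batch(chunks[start:start + batch_size], n_classes, dtype)
        model.forward(x, training=True)
    for bn in bns:
        bn.momentum = 0.1


def predict_chunks(model: nn.Sequential, chunks: list[Chunk],
                   batch_size: int = 8) -> np.ndarray:
    """Per-chunk class-probability vectors, shape (n_chunks, n_classes)."""
    if not chunks:
        return np.zeros((0, model.config.n_classes))
    out = []
    for i in range(0, len(chunks), batch_size):
        x, _ = _assemble_batch(chunks[i:i + batch_size],
                               model.config.n_classes, np.float32)
        out.append(nn.softmax(model.forward(x, training=False)))
    return np.concatenate(out, axis=0)


def predict_labels(model: nn.Sequential, chunks: list[Chunk],
                   batch_size: int = 8) -> np.ndarray:
    return predict_chunks(model, chunks, batch_size).argmax(axis=1)


def vote_video(chunk_labels) -> FlowCondition:
    """Majority vote over one video's chunk labels; ties go to the lower-flow class."""
    labels = [FlowCondition(int(l)) for l in chunk_labels]
    if not labels:
        raise ValueError("cannot vote on an empty label list")
    counts: dict[FlowCondition, int] = {}
    for l in labels:
        counts[l] = counts.get(l, 0) + 1
    top = max(counts.values())
    return min(l for l, c in counts.items() if c == top)


def save_checkpoint(model: nn.Sequential, path, train_config: TrainConfig | None = None):
    """Serialise weights plus a JSON sidecar of the model/train configs."""
    path = Path(path)
    state = {
        "params": model.named_params(),
        "running": {
            f"{i}.{attr}": getattr(layer, attr)
            for i, layer in enumerate(model.layers)
            if isinstance(layer, nn.BatchNorm3d)
            for attr in ("running_mean", "running_var")
        },
        "config": asdict(model.config),
        "input_shape": model.input_shape,
    }
    with open(path, "wb") as f:
        pickle.dump(state, f)
    sidecar = {"model_config": asdict(model.config),
               "input_shape": list(model.input_shape)}
    if train_config is not None:
        sidecar["train_config"] = asdict(train_config)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> nn.Sequential:
    with open(path, "rb") as f:
        state = pickle.load(f)
    cfg = ModelConfig(**{**state["config"],
                         "block_channels": tuple(state["config"]["block_channels"]),
                         "stem_kernel": tuple(state["config"]["stem_kernel"]),
                         "stem_stride": tuple(state["config"]["stem_stride"]),
                         "stem_padding": tuple(state["config"]["stem_padding"])})
    model = build_model(cfg, tuple(state["input_shape"]))
    for k, p in model.named_params().items():
        p[...] = state["params"][k]
    for key, val in state["running"].items():
        idx, attr = key.split(".", 1)
        setattr(model.layers[int(idx)], attr, val)
    return model
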