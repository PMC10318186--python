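"""The residual 1D convolutional balance classifier.

Architecture: the 20-frame, J-joint, 3-axis input tensor is arranged as a
length-20 time series with 3*J channels (channel = joint-major, axis-minor),
passed through ``n_blocks`` residual blocks (conv k1 -> BN -> ReLU ->
conv k2 -> BN -> ReLU -> conv k3 -> BN -> ReLU, input added to the branch
output, with a 1-wide projection when channel counts differ), then dropout,
global average pooling over time, and a dense layer to 3 class scores.

Defaults follow the published setup: kernels (5, 3, 1), 64 channels,
3 residual blocks, cross-entropy loss, Adam at learning rate 1e-4, and
early stopping on validation loss with best-epoch weight restoration.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import (
    Dense, Dropout, GlobalAvgPool, ResidualBlock, make_optimizer,
)
from .nn.layers import DTYPE
from .preprocessing import PreprocessedSample, samples_to_arrays

N_CLASSES = 3


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the classifier and its training loop."""

    kernel_sizes: tuple[int, int, int] = (5, 3, 1)
    channels: int = 64
    n_blocks: int = 3
    dropout_rate: float = 0.5
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    max_epochs: int = 300
    patience: int = 20
    batch_size: int = 16
    seed: int = 0
    n_classes: int = N_CLASSES
    activation: str = "relu"  # 'identity' turns the net affine (test hook)

    def __post_init__(self) -> None:
        if len(self.kernel_sizes) != 3:
            raise ValueError("kernel_sizes must be a triple")
        for k in self.kernel_sizes:
            if k < 1 or k % 2 == 0:
                raise ValueError(f"kernel sizes must be odd and >= 1, got {k}")
        if self.channels < 1 or self.n_blocks < 1:
            raise ValueError("channels and n_blocks must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.optimizer.lower() not in ("adam", "sgd", "rmsprop"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainingHistory:
    """Per-epoch losses and the early-stopping outcome."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


class BalanceClassifier:
    """A residual DCNN instance (possibly untrained) plus its geometry."""

    def __init__(self, config: ModelConfig, n_joints: int) -> None:
        if n_joints < 1:
            raise ValueError("n_joints must be >= 1")
        self.config = config
        self.n_joints = n_joints
        self.n_channels_in = 3 * n_joints
        rng = np.random.default_rng(config.seed)
        self.blocks: list[ResidualBlock] = []
        c_in = self.n_channels_in
        for _ in range(config.n_blocks):
            self.blocks.append(ResidualBlock(
                c_in, config.channels, tuple(config.kernel_sizes), rng,
                activation=config.activation,
            ))
            c_in = config.channels
        self.dropout = Dropout(config.dropout_rate)
        self.pool = GlobalAvgPool()
        self.dense = Dense(config.channels, config.n_classes, rng)
        self.layers = [*self.blocks, self.dropout, self.pool, self.dense]
        self.params = [p for l in self.layers for p in l.params]
        self.grads = [g for l in self.layers for g in l.grads]
        self.history: TrainingHistory | None = None

    # ---- tensor plumbing -------------------------------------------------

    def to_channels(self, X: np.ndarray) -> np.ndarray:
        """(n, T, J, 3) -> (n, 3J, T), channel index = joint*3 + axis."""
        n, t, j, d = X.shape
        if j != self.n_joints or d != 3:
            raise ValueError(
                f"sample geometry (J={j}, D={d}) does not match model "
                f"geometry (J={self.n_joints}, D=3)"
            )
        return np.ascontiguousarray(
            X.transpose(0, 2, 3, 1).reshape(n, 3 * j, t), dtype=DTYPE
        )

    def from_channels(self, A: np.ndarray) -> np.ndarray:
        """(n, 3J, T) -> (n, T, J, 3): inverse of :meth:`to_channels`."""
        n, c, t = A.shape
        return A.reshape(n, self.n_joints, 3, t).transpose(0, 3, 1, 2)

    # ---- forward / loss --------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def logits(self, samples: list[PreprocessedSample] | np.ndarray) -> np.ndarray:
        X = samples if isinstance(samples, np.ndarray) \
            else np.stack([s.tensor for s in samples])
        return self.forward(self.to_channels(X), training=False)

    def _state_arrays(self) -> list[np.ndarray]:
        # learned parameters plus BN running statistics: everything the
        # inference-mode forward pass depends on
        arrays = list(self.params)
        for blk in self.blocks:
            for bn in (blk.bn1, blk.bn2, blk.bn3):
                arrays.extend((bn.running_mean, bn.running_var))
        return arrays

    def snapshot(self) -> list[np.ndarray]:
        return [a.copy() for a in self._state_arrays()]

    def restore(self, snap: list[np.ndarray]) -> None:
        for a, s in zip(self._state_arrays(), snap):
            a[...] = s


def build_classifier(config: ModelConfig, n_joints: int) -> BalanceClassifier:
    """Construct an untrained classifier for the given joint count."""
    return BalanceClassifier(config, n_joints)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = len(labels)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(logits.dtype)


def _check_split(train: list[PreprocessedSample], val: list[PreprocessedSample]) -> None:
    if not train or not val:
        raise ValueError("train and validation sets must be non-empty")
    for s in (*train, *val):
        if s.label not in range(N_CLASSES):
            raise ValueError(f"label {s.label} outside 0..{N_CLASSES - 1}")
    overlap = {s.subject_id for s in train} & {s.subject_id for s in val}
    if overlap:
        raise ValueError(f"train/validation subjects overlap: {sorted(overlap)}")


def train_classifier(
    model: BalanceClassifier,
    train: list[PreprocessedSample],
    val: list[PreprocessedSample],
    config: ModelConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[BalanceClassifier, TrainingHistory]:
    """Train with mini-batch cross-entropy and early stopping.

    Stops when the validation loss has not improved for ``patience`` epochs
    (or at ``max_epochs``) and restores the parameters of the best epoch.
    """
    config = config or model.config
    _check_split(train, val)
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    model.dropout.rng = rng

    Xtr, ytr, _ = samples_to_arrays(train)
    Xva, yva, _ = samples_to_arrays(val)
    Atr = model.to_channels(Xtr)
    Ava = model.to_channels(Xva)

    opt = make_optimizer(config.optimizer, model.params, model.grads,
                         config.learning_rate)
    history = TrainingHistory()
    best_loss = np.inf
    best_snap = model.snapshot()
    since_best = 0

    n = len(train)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.forward(Atr[idx], training=True)
            loss, gl = cross_entropy(logits, ytr[idx])
            epoch_loss += loss * len(idx)
            g = gl
            for layer in reversed(model.layers):
                g = layer.backward(g)
            opt.step()
        history.train_loss.append(epoch_loss / n)

        val_logits = model.forward(Ava, training=False)
        val_loss, _ = cross_entropy(val_logits, yva)
        val_acc = float((val_logits.argmax(axis=1) == yva).mean())
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)

        if val_loss < best_loss:
            best_loss = val_loss
            best_snap = model.snapshot()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    history.stopped_epoch = len(history.train_loss) - 1
    model.restore(best_snap)
    model.history = history
    return model, history


def predict(
    model: BalanceClassifier,
    samples: list[PreprocessedSample] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels (ties -> smaller class index)."""
    logits = model.logits(samples)
    probs = softmax(logits.astype(np.float64))
    return probs, probs.argmax(axis=1)


def save_model(model: BalanceClassifier, path) -> None:
    """Serialize config, geometry, learned parameters and BN statistics."""
    import json
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param_{i}": p for i, p in enumerate(model.params)}
    bn_stats = {}
    for bi, blk in enumerate(model.blocks):
        for name in ("bn1", "bn2", "bn3"):
            bn = getattr(blk, name)
            bn_stats[f"block{bi}_{name}_mean"] = bn.running_mean
            bn_stats[f"block{bi}_{name}_var"] = bn.running_var
    cfg = dict(model.config.__dict__)
    cfg["kernel_sizes"] = list(cfg["kernel_sizes"])
    meta = json.dumps({"config": cfg, "n_joints": model.n_joints})
    np.savez(path, __meta__=np.array(meta), **arrays, **bn_stats)


def load_model(path) -> BalanceClassifier:
    """Rebuild a classifier saved by :func:`save_model`."""
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        cfg_d = meta["config"]
        cfg_d["kernel_sizes"] = tuple(cfg_d["kernel_sizes"])
        model = BalanceClassifier(ModelConfig(**cfg_d), meta["n_joints"])
        for i, p in enumerate(model.params):
            p[...] = data[f"param_{i}"]
        for bi, blk in enumerate(model.blocks):
            for name in ("bn1", "bn2", "bn3"):
                bn = getattr(blk, name)
                bn.running_mean[...] = data[f"block{bi}_{name}_mean"]
                bn.running_var[...] = data[f"block{bi}_{name}_var"]
    return model
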