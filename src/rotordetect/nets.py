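"""Classifier architectures and training procedure.

Three binary rotor classifiers operate on fixed-length normalized
windows:

* ``SimpleSpec`` — a dense baseline (flatten, 128-64-1 units, rectifier
  activations, sigmoid output).
* ``AticnnSpec`` — a deep 1-D CNN in the style of time-incremental ECG
  classifiers: 13 convolution layers of kernel 3 in five blocks with
  channel progression 64-128-256-256-256 and pooling between blocks,
  followed by two LSTM layers and a sigmoid unit.
* ``CrnnSpec`` — the convolutional-recurrent network: symmetric 37-sample
  time padding, three convolution blocks with rectangular kernels
  (long side along time), batch normalization, leaky rectifiers,
  boundary-truncating max pools of growing size, 30% dropout, then two
  32-unit GRU layers and a sigmoid unit.

``forward_shapes`` propagates shapes in closed form (padding adds 2*37
time samples, size-preserving convolutions keep spatial extent, pools
map n to floor((n-k)/s)+1 per axis); ``build`` instantiates the model so
that its actual layer outputs match.  Training uses Adam with a
learning-rate grid {1e-2, 1e-3, 1e-4}, binary cross-entropy, batch size
32 and early stopping on validation accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .containers import LabeledWindow

__all__ = [
    "CrnnSpec",
    "SimpleSpec",
    "AticnnSpec",
    "TrainConfig",
    "forward_shapes",
    "build",
    "train",
    "predict",
    "prepare_input",
    "windows_to_arrays",
]


@dataclass(frozen=True)
class CrnnSpec:
    """Convolutional-recurrent rotor classifier.

    ``time_major_kernel=True`` puts the long kernel side (23) along the
    time axis — rectangular kernels capture longer temporal context.
    The flipped orientation is available for comparison; the shape chain
    is identical either way because convolutions preserve size.
    """

    pad_time: int = 37
    conv_filters: tuple[int, ...] = (32, 64, 64)
    kernel_long: int = 23
    kernel_short: int = 5
    time_major_kernel: bool = True
    pools: tuple[tuple[int, int, int, int], ...] = (
        (2, 2, 2, 1),
        (3, 3, 3, 3),
        (4, 4, 4, 4),
    )  # (kh, kw, sh, sw) with h = time axis
    dropout: float = 0.3
    leaky_alpha: float = 0.3
    gru_units: tuple[int, int] = (32, 32)

    @property
    def kernel_hw(self) -> tuple[int, int]:
        if self.time_major_kernel:
            return (self.kernel_long, self.kernel_short)
        return (self.kernel_short, self.kernel_long)


@dataclass(frozen=True)
class SimpleSpec:
    """Dense baseline: exactly three fully connected layers."""

    dense_units: tuple[int, int, int] = (128, 64, 1)


@dataclass(frozen=True)
class AticnnSpec:
    """Deep 1-D CNN (13 conv layers) + 2 LSTM layers.

    Electrodes enter as input channels; convolution runs along time.
    """

    block_layers: tuple[int, ...] = (2, 2, 3, 3, 3)
    block_channels: tuple[int, ...] = (64, 128, 256, 256, 256)
    kernel: int = 3
    pool: tuple[int, int] = (2, 2)  # (k, s) along time after each block
    lstm_units: tuple[int, int] = (32, 32)
    dropout: float = 0.0

    @property
    def n_conv_layers(self) -> int:
        return sum(self.block_layers)


@dataclass
class TrainConfig:
    """Optimization settings: Adam, lr grid, BCE loss, batch 32.

    ``epochs`` and ``patience`` (in validation rounds) are artifact
    choices; ``val_every_steps=None`` validates once per epoch.
    """

    lr_grid: tuple[float, ...] = (1e-2, 1e-3, 1e-4)
    batch_size: int = 32
    epochs: int = 50
    patience: int = 10
    val_every_steps: int | None = None
    max_steps_per_epoch: int | None = None
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if not self.lr_grid:
            raise ValueError("learning-rate grid must be non-empty")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


def _pool_out(n: int, k: int, s: int) -> int:
    m = (n - k) // s + 1
    if m < 1:
        raise ValueError(f"axis of length {n} too short for pool {k}/{s}")
    return m


def forward_shapes(spec, input_shape: tuple[int, int]) -> list[tuple[str, tuple]]:
    """Closed-form per-layer output shapes for an (time, channels) input."""
    t, c = input_shape
    if isinstance(spec, CrnnSpec):
        shapes: list[tuple[str, tuple]] = [("input", (t, c, 1))]
        t = t + 2 * spec.pad_time
        shapes.append(("zero_pad", (t, c, 1)))
        prev = 1
        for i, f in enumerate(spec.conv_filters):
            shapes.append((f"conv{i + 1}", (t, c, f)))
            kh, kw, sh, sw = spec.pools[i]
            t = _pool_out(t, kh, sh)
            c = _pool_out(c, kw, sw)
            shapes.append((f"pool{i + 1}", (t, c, f)))
            prev = f
        shapes.append(("recurrent_input", (t, c * prev)))
        for i, u in enumerate(spec.gru_units[:-1]):
            shapes.append((f"gru{i + 1}", (t, u)))
        shapes.append((f"gru{len(spec.gru_units)}", (spec.gru_units[-1],)))
        shapes.append(("dense", (1,)))
        return shapes
    if isinstance(spec, SimpleSpec):
        shapes = [("input", (t, c)), ("flatten", (t * c,))]
        for i, u in enumerate(spec.dense_units):
            shapes.append((f"dense{i + 1}", (u,)))
        return shapes
    if isinstance(spec, AticnnSpec):
        shapes = [("input", (t, c))]
        ch = c
        for b, (n_l, f) in enumerate(zip(spec.block_layers, spec.block_channels)):
            for _ in range(n_l):
                shapes.append((f"conv_b{b + 1}", (t, f)))
            k, s = spec.pool
            t = _pool_out(t, k, s)
            shapes.append((f"pool_b{b + 1}", (t, f)))
            ch = f
        for i, u in enumerate(spec.lstm_units[:-1]):
            shapes.append((f"lstm{i + 1}", (t, u)))
        shapes.append((f"lstm{len(spec.lstm_units)}", (spec.lstm_units[-1],)))
        shapes.append(("dense", (1,)))
        return shapes
    raise TypeError(f"unknown spec {type(spec).__name__}")


def build(spec, input_shape: tuple[int, int], seed: int = 0) -> nn.Model:
    """Instantiate a model for (time, channels) inputs.

    Identical seeds give identical initial parameters.  The model's
    layer-by-layer output shapes reproduce ``forward_shapes``.
    """
    forward_shapes(spec, input_shape)  # validates feasibility
    t, c = input_shape
    rng = np.random.default_rng(seed)
    drop_rng = np.random.default_rng(np.random.default_rng(seed + 1).integers(2**31))
    if isinstance(spec, CrnnSpec):
        kh, kw = spec.kernel_hw
        layers: list[nn.Layer] = [
            nn.ZeroPadTime(spec.pad_time),
            nn.BatchNorm(1),
            nn.Dropout(spec.dropout, drop_rng),
        ]
        prev = 1
        tt, cc = t + 2 * spec.pad_time, c
        for i, f in enumerate(spec.conv_filters):
            layers += [
                nn.Conv2D(kh, kw, prev, f, rng),
                nn.BatchNorm(f),
                nn.LeakyReLU(spec.leaky_alpha),
                nn.MaxPool2D(*spec.pools[i]),
                nn.Dropout(spec.dropout, drop_rng),
            ]
            pkh, pkw, psh, psw = spec.pools[i]
            tt = _pool_out(tt, pkh, psh)
            cc = _pool_out(cc, pkw, psw)
            prev = f
        layers.append(nn.FoldWidth())
        feat = cc * prev
        layers.append(nn.GRU(feat, spec.gru_units[0], rng, return_sequences=True))
        layers.append(nn.GRU(spec.gru_units[0], spec.gru_units[1], rng))
        layers.append(nn.Dropout(spec.dropout, drop_rng))
        layers.append(nn.Dense(spec.gru_units[1], 1, rng))
        return nn.Model(layers, (t, c, 1))
    if isinstance(spec, SimpleSpec):
        layers = [nn.Flatten()]
        prev_n = t * c
        for i, u in enumerate(spec.dense_units):
            layers.append(nn.Dense(prev_n, u, rng))
            if i < len(spec.dense_units) - 1:
                layers.append(nn.ReLU())
            prev_n = u
        return nn.Model(layers, (t, c))
    if isinstance(spec, AticnnSpec):
        # electrodes as channels: internal layout (N, T, 1, C)
        layers = []
        prev = c
        for b, (n_l, f) in enumerate(zip(spec.block_layers, spec.block_channels)):
            for _ in range(n_l):
                layers += [nn.Conv2D(spec.kernel, 1, prev, f, rng), nn.ReLU()]
                prev = f
            k, s = spec.pool
            layers.append(nn.MaxPool2D(k, 1, s, 1))
        layers.append(nn.FoldWidth())
        layers.append(nn.LSTM(prev, spec.lstm_units[0], rng, return_sequences=True))
        layers.append(nn.LSTM(spec.lstm_units[0], spec.lstm_units[1], rng))
        if spec.dropout > 0:
            layers.append(nn.Dropout(spec.dropout, drop_rng))
        layers.append(nn.Dense(spec.lstm_units[1], 1, rng))
        return nn.Model(layers, (t, 1, c))
    raise TypeError(f"unknown spec {type(spec).__name__}")


def prepare_input(windows: np.ndarray, spec) -> np.ndarray:
    """Stack (channels, samples) windows into the model's batch layout."""
    x = np.asarray(windows, dtype=np.float32)
    if x.ndim != 3:
        raise ValueError("expected (n, channels, samples)")
    xt = np.transpose(x, (0, 2, 1))  # (N, time, channels)
    if isinstance(spec, CrnnSpec):
        return xt[..., None]  # (N, T, C, 1)
    if isinstance(spec, AticnnSpec):
        return xt[:, :, None, :]  # (N, T, 1, C)
    return xt


def windows_to_arrays(
    windows: list[LabeledWindow], spec
) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) arrays in model layout from a list of labeled windows."""
    x = np.stack([w.x for w in windows])
    y = np.array([w.y for w in windows], dtype=np.float64)
    return prepare_input(x, spec), y


def _accuracy(model: nn.Model, x: np.ndarray, y: np.ndarray,
              batch_size: int) -> float:
    p = model.predict_proba(x, batch_size)
    return float(np.mean((p >= 0.5) == (y >= 0.5)))


def train(
    model: nn.Model,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
) -> tuple[nn.Model, dict]:
    """Grid-search learning rates; early-stop on validation accuracy.

    For every learning rate the model restarts from its initial weights,
    trains with Adam on binary cross-entropy in batches of
    ``cfg.batch_size``, and keeps the weights of its best validation
    round.  The returned model carries the best weights across the grid;
    the history records per-round loss and validation accuracy per
    learning rate.
    """
    x_tr, y_tr = train_set
    x_va, y_va = val_set
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("empty training or validation set")
    init = model.get_weights()
    history: dict = {"lr": {}, "best_lr": None, "best_val_accuracy": -1.0}
    best_weights = None
    for lr in cfg.lr_grid:
        model.set_weights(init)
        opt = nn.Adam(model, lr=lr)
        rng = np.random.default_rng(cfg.seed)
        rounds: list[dict] = []
        lr_best_acc, lr_best_w, since_best = -1.0, None, 0
        step = 0
        last_eval = 0
        stop = False

        def eval_round(losses: list[float]) -> bool:
            """Validation round; returns True when patience is exhausted."""
            nonlocal lr_best_acc, lr_best_w, since_best, last_eval
            acc = _accuracy(model, x_va, y_va, cfg.batch_size)
            rounds.append(
                {"step": step, "loss": float(np.mean(losses)), "val_accuracy": acc}
            )
            last_eval = step
            if cfg.verbose:
                print(f"lr={lr:g} step={step} loss={np.mean(losses):.4f} "
                      f"val_acc={acc:.3f}")
            if acc > lr_best_acc:
                lr_best_acc, lr_best_w, since_best = acc, model.get_weights(), 0
                return False
            since_best += 1
            return since_best >= cfg.patience

        for epoch in range(cfg.epochs):
            order = rng.permutation(len(x_tr))
            losses: list[float] = []
            n_steps = len(order) // cfg.batch_size or 1
            if cfg.max_steps_per_epoch is not None:
                n_steps = min(n_steps, cfg.max_steps_per_epoch)
            for s in range(n_steps):
                idx = order[s * cfg.batch_size : (s + 1) * cfg.batch_size]
                losses.append(model.train_step(x_tr[idx], y_tr[idx], opt))
                step += 1
                if cfg.val_every_steps and step % cfg.val_every_steps == 0:
                    if eval_round(losses):
                        stop = True
                        break
            if not stop and step > last_eval:  # epoch-end round
                stop = eval_round(losses)
            if stop:
                break
        history["lr"][lr] = rounds
        if lr_best_acc > history["best_val_accuracy"]:
            history["best_val_accuracy"] = lr_best_acc
            history["best_lr"] = lr
            best_weights = lr_best_w
    model.set_weights(best_weights if best_weights is not None else init)
    return model, history


def predict(
    model: nn.Model, x: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and thresholded labels (label = p >= threshold)."""
    p = model.predict_proba(x)
    return (p >= threshold).astype(int), p
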