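"""The multi-scale, multi-task blood-pressure network (MST-net).

One shared stem (Conv k=15 -> max-pool 3) feeds three parallel convolutional
streams with kernel sizes 5, 7, and 9 — the same input seen at three
receptive-field scales. Each stream stacks four modules of two convolutions
(each followed by batch norm + ReLU) with 64/128/256/512 filters, ends in
global average pooling and a 512-wide fully-connected layer; the three
512-vectors concatenate into a 1536-feature representation, pass through a
256-wide hidden layer, and a 3-neuron linear head emits SBP, DBP, and MAP
simultaneously (multi-task regression with fully shared weights).

Temporal downsampling: the first convolution of each module uses stride 2,
so an 8-s, 1000-sample segment is reduced to ~20 time steps before pooling.

Training minimizes the joint mean squared error over the three tasks plus an
L2 penalty on convolution/FC weights, with a step-decayed learning rate
(decay once every 5 epochs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

__all__ = [
    "MstNetConfig",
    "TrainConfig",
    "MstNet",
    "build_model",
    "multitask_mse",
    "multitask_mse_grad",
    "l2_penalty",
    "lr_schedule",
    "count_parameters",
]


@dataclass
class MstNetConfig:
    """Every architectural hyperparameter of the network."""

    input_channels: int = 2
    input_length: int = 1000
    stem_kernel: int = 15
    stem_filters: int = 32
    stem_pool: int = 3
    stream_kernels: tuple[int, ...] = (5, 7, 9)
    modules_per_stream: int = 4
    convs_per_module: int = 2
    module_filters: tuple[int, ...] = (64, 128, 256, 512)
    stream_fc: int = 512
    head_fc: int = 256
    outputs: int = 3
    module_stride: int = 2  # stride of the first convolution in each module

    def __post_init__(self) -> None:
        self.stream_kernels = tuple(self.stream_kernels)
        self.module_filters = tuple(self.module_filters)
        if len(self.module_filters) != self.modules_per_stream:
            raise ValueError("module_filters must list one width per module")
        if self.outputs != 3:
            raise ValueError("the network jointly estimates SBP, DBP, and MAP")
        if len(self.stream_kernels) < 1:
            raise ValueError("at least one stream is required")
        min_len = self.stem_pool * self.module_stride**self.modules_per_stream
        if self.input_length < min_len:
            raise ValueError(
                f"input_length {self.input_length} too short for the "
                f"pooling/stride plan; minimum is {min_len}"
            )

    @property
    def concat_width(self) -> int:
        """Feature width presented to the first head FC layer."""
        return len(self.stream_kernels) * self.stream_fc

    @classmethod
    def reduced(cls) -> "MstNetConfig":
        """A narrow variant for CPU-scale experiments and tests."""
        return cls(stem_filters=8, module_filters=(8, 16, 32, 64), stream_fc=64, head_fc=64)


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    ``gamma`` (LR decay per 5-epoch block) and ``l2_lambda`` have no
    published values; the defaults here are the package's own choices and
    both are freely configurable.
    """

    batch_size: int = 100
    epochs: int = 150
    lr_base: float = 0.01
    gamma: float = 0.5
    l2_lambda: float = 1e-4
    val_fraction: float = 0.1
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must lie in (0, 1]")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be non-negative")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must lie in [0, 1)")


def _conv_block(in_ch, out_ch, k, stride, rng) -> list[nn.Layer]:
    return [nn.Conv1d(in_ch, out_ch, k, stride=stride, rng=rng), nn.BatchNorm1d(out_ch), nn.ReLU()]


class MstNet:
    """The assembled network; see the module docstring for the topology."""

    def __init__(self, config: MstNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.stem = nn.Sequential(
            *_conv_block(c.input_channels, c.stem_filters, c.stem_kernel, 1, rng),
            nn.MaxPool1d(c.stem_pool),
        )
        self.streams = []
        for k in c.stream_kernels:
            layers: list[nn.Layer] = []
            prev = c.stem_filters
            for filters in c.module_filters:
                for j in range(c.convs_per_module):
                    stride = c.module_stride if j == 0 else 1
                    layers += _conv_block(prev, filters, k, stride, rng)
                    prev = filters
            layers += [nn.GlobalAvgPool1d(), nn.Linear(prev, c.stream_fc, rng=rng), nn.ReLU()]
            self.streams.append(nn.Sequential(*layers))
        self.head = nn.Sequential(
            nn.Linear(c.concat_width, c.head_fc, rng=rng),
            nn.ReLU(),
            nn.Linear(c.head_fc, c.outputs, rng=rng),
        )

    def params(self) -> list[nn.Param]:
        out = self.stem.params()
        for s in self.streams:
            out += s.params()
        return out + self.head.params()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        c = self.config
        if x.shape[1:] != (c.input_channels, c.input_length):
            raise ValueError(
                f"expected input (n, {c.input_channels}, {c.input_length}), got {x.shape}"
            )
        h = self.stem.forward(x, training)
        feats = [s.forward(h, training) for s in self.streams]
        self._concat_width = sum(f.shape[1] for f in feats)
        return self.head.forward(np.concatenate(feats, axis=1), training)

    __call__ = forward

    def backward(self, grad: np.ndarray) -> None:
        dcat = self.head.backward(grad)
        splits = np.cumsum([self.config.stream_fc] * (len(self.streams) - 1))
        dstem = None
        for stream, g in zip(self.streams, np.split(dcat, splits, axis=1)):
            d = stream.backward(g)
            dstem = d if dstem is None else dstem + d
        self.stem.backward(dstem)

    def shape_trace(self, batch: int = 1) -> list[tuple[str, tuple[int, ...]]]:
        """Layer-by-layer output shapes for one forward pass."""
        c = self.config
        x = np.zeros((batch, c.input_channels, c.input_length))
        trace: list[tuple[str, tuple[int, ...]]] = [("input", x.shape)]
        h = x
        for layer in self.stem.layers:
            h = layer.forward(h, False)
            trace.append((f"stem.{type(layer).__name__}", h.shape))
        feats = []
        for si, stream in enumerate(self.streams):
            g = h
            for layer in stream.layers:
                g = layer.forward(g, False)
                trace.append((f"stream{si}(k={c.stream_kernels[si]}).{type(layer).__name__}", g.shape))
            feats.append(g)
        cat = np.concatenate(feats, axis=1)
        trace.append(("concat", cat.shape))
        g = cat
        for layer in self.head.layers:
            g = layer.forward(g, False)
            trace.append((f"head.{type(layer).__name__}", g.shape))
        return trace

    @property
    def concat_width(self) -> int:
        return self.config.concat_width


def build_model(config: MstNetConfig | None = None, seed: int = 0) -> MstNet:
    """Construct an MST-net with seeded Kaiming fan-in initialization."""
    return MstNet(config or MstNetConfig(), seed=seed)


def multitask_mse(pred: np.ndarray, ref: np.ndarray) -> float:
    """Joint MSE: mean over segments of the summed squared error of the
    three tasks (SBP, DBP, MAP)."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    return float(np.mean(np.sum((ref - pred) ** 2, axis=1)))


def multitask_mse_grad(pred: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """d(multitask_mse)/d(pred)."""
    return 2.0 * (pred - ref) / pred.shape[0]


def l2_penalty(model: MstNet, l2_lambda: float) -> float:
    """lambda * sum of squared convolution/FC weights (biases and batch-norm
    parameters exempt)."""
    if l2_lambda < 0:
        raise ValueError("l2_lambda must be non-negative")
    if l2_lambda == 0:
        return 0.0
    return float(l2_lambda * sum(np.sum(p.value**2) for p in model.params() if p.is_weight))


def lr_schedule(lr_base: float, gamma: float, epoch: int) -> float:
    """Step decay: lr_base * gamma ** floor(epoch / 5)."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return lr_base * gamma ** (epoch // 5)


def count_parameters(model: MstNet) -> int:
    """Total trainable scalar parameters."""
    return int(sum(p.value.size for p in model.params()))
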