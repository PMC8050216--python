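"""The fully convolutional sleep-staging network.

The model is a 1-D U-Net: an encoder of ``depth`` blocks (conv k=9 →
ELU → batch-norm → skip tap → max-pool 2), an optional bottleneck block,
a mirrored decoder (nearest-neighbour ×2 upsample → conv k=2 → ELU →
batch-norm → concat skip → conv k=9 → ELU → batch-norm), a pointwise
projection to K stage channels (the high-frequency score map at the
internal 128 Hz rate), and a segment classifier that mean-pools the score
map over windows of ``i`` samples and applies two pointwise convolutions
with a softmax.

The classifier's weights do not depend on ``i``: the output frequency is
an inference-time argument, from one label per 30 s down to one label per
sample.  Filter counts grow by ⌊c·√2⌋ per encoder block starting at
``base_filters`` and shrink on the same schedule in the decoder.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from ._stages import N_STAGES
from . import nn as _nn
from .nn import (
    Adam,
    BatchNorm1d,
    Conv1d,
    CropRight,
    ELU,
    MaxPool2,
    SegmentMeanPool,
    UpsampleNearest2,
    softmax,
)

__all__ = [
    "ModelConfig",
    "StagePosterior",
    "encoder_filter_sequence",
    "min_input_length",
    "receptive_field",
    "count_parameters",
    "build_model",
    "USleepNet",
]

_SQRT2 = math.sqrt(2.0)


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the full-scale configuration: 12 encoder/decoder blocks,
    5 base filters growing by √2, kernel 9 convolutions, width-2 pooling,
    two input channels (one EEG + one EOG) at an internal 128 Hz rate and
    K = 5 sleep stages.
    """

    depth: int = 12
    base_filters: int = 5
    filter_growth: float = _SQRT2
    conv_kernel: int = 9
    decoder_up_kernel: int = 2
    pool_kernel: int = 2
    n_stages: int = N_STAGES
    in_channels: int = 2
    internal_rate: float = 128.0
    classifier_hidden: int | None = None  # None → n_stages
    merge_kernel: int = 9
    with_bottleneck: bool = True

    def __post_init__(self):
        if self.depth < 1 or self.base_filters < 1:
            raise ValueError("depth and base_filters must be ≥ 1")
        if self.conv_kernel < 1 or self.pool_kernel < 2:
            raise ValueError("invalid kernel configuration")

    @property
    def hidden(self) -> int:
        return self.classifier_hidden or self.n_stages

    def segment_samples(self, period_s: float = 30.0) -> int:
        """Samples per output label for a given label period."""
        i = self.internal_rate * period_s
        if abs(i - round(i)) > 1e-9:
            raise ValueError(f"period {period_s}s is not a whole number of samples at "
                             f"{self.internal_rate} Hz")
        return int(round(i))


@dataclass
class StagePosterior:
    """T×K row-stochastic stage confidences for one channel pair."""

    values: np.ndarray  # (T, K)
    segment_samples: int  # i
    origin: tuple = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("posterior must be a T×K matrix")

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    def argmax_labels(self) -> np.ndarray:
        """Per-segment argmax (ties → lowest stage index)."""
        return self.values.argmax(axis=1).astype(np.int8)


def encoder_filter_sequence(c1: int, depth: int, growth: float = _SQRT2) -> list[int]:
    """Filter counts per encoder block: c1, ⌊c1·g⌋, ⌊⌊c1·g⌋·g⌋, ..."""
    if c1 < 1 or depth < 1:
        raise ValueError("c1 and depth must be ≥ 1")
    seq = [int(c1)]
    for _ in range(depth - 1):
        seq.append(int(math.floor(seq[-1] * growth)))
    return seq


def min_input_length(config: ModelConfig) -> int:
    """Recommended minimum input length: one sample left at the bottleneck,
    i.e. pool_kernel ** depth (4096 for the default 12×2 configuration)."""
    return config.pool_kernel ** config.depth


def receptive_field(config: ModelConfig) -> int:
    """Theoretical receptive field (in input samples) of the deepest
    encoder convolution, by the RF ← RF + (k−1)·jump recursion."""
    rf, jump = 1, 1
    for block in range(config.depth):
        rf += (config.conv_kernel - 1) * jump
        if block < config.depth - 1 or config.with_bottleneck:
            # the pool only widens the field of a convolution that follows it
            rf += (config.pool_kernel - 1) * jump
            jump *= config.pool_kernel
    if config.with_bottleneck:
        rf += (config.conv_kernel - 1) * jump
    return rf


def _conv_params(cin: int, cout: int, k: int) -> int:
    return cout * cin * k + cout


def count_parameters(config: ModelConfig) -> int:
    """Closed-form count of trainable scalars (conv weights/biases and
    batch-norm scale/shift) of the network :func:`build_model` constructs."""
    enc = encoder_filter_sequence(config.base_filters, config.depth, config.filter_growth)
    total = 0
    cin = config.in_channels
    for f in enc:
        total += _conv_params(cin, f, config.conv_kernel) + 2 * f
        cin = f
    if config.with_bottleneck:
        f = int(math.floor(enc[-1] * config.filter_growth))
        total += _conv_params(enc[-1], f, config.conv_kernel) + 2 * f
        cin = f
    for f in reversed(enc):
        total += _conv_params(cin, f, config.decoder_up_kernel) + 2 * f
        total += _conv_params(2 * f, f, config.merge_kernel) + 2 * f
        cin = f
    total += _conv_params(enc[0], config.n_stages, 1)  # score-map projection
    total += _conv_params(config.n_stages, config.hidden, 1)
    total += _conv_params(config.hidden, config.n_stages, 1)
    return total


class USleepNet:
    """Encoder–decoder–segment-classifier network (see module docstring).

    Parameters are float32 numpy arrays; forward/backward run on a single
    CPU.  Use :func:`build_model` to construct one.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        enc_filters = encoder_filter_sequence(config.base_filters, config.depth,
                                              config.filter_growth)
        self.enc_filters = enc_filters

        self.encoder = []
        cin = config.in_channels
        for f in enc_filters:
            self.encoder.append({
                "conv": Conv1d(cin, f, config.conv_kernel, rng),
                "elu": ELU(),
                "bn": BatchNorm1d(f),
                "pool": MaxPool2(),
            })
            cin = f

        self.bottleneck = None
        if config.with_bottleneck:
            f = int(math.floor(enc_filters[-1] * config.filter_growth))
            self.bottleneck = {
                "conv": Conv1d(cin, f, config.conv_kernel, rng),
                "elu": ELU(),
                "bn": BatchNorm1d(f),
            }
            cin = f

        self.decoder = []
        for f in reversed(enc_filters):
            self.decoder.append({
                "up": UpsampleNearest2(),
                "crop": CropRight(),
                "conv_up": Conv1d(cin, f, config.decoder_up_kernel, rng),
                "elu_up": ELU(),
                "bn_up": BatchNorm1d(f),
                "conv_merge": Conv1d(2 * f, f, config.merge_kernel, rng),
                "elu_merge": ELU(),
                "bn_merge": BatchNorm1d(f),
            })
            cin = f

        self.project = Conv1d(enc_filters[0], config.n_stages, 1, rng)
        self.seg_pool = SegmentMeanPool()
        self.cls_conv1 = Conv1d(config.n_stages, config.hidden, 1, rng)
        self.cls_elu = ELU()
        self.cls_conv2 = Conv1d(config.hidden, config.n_stages, 1, rng)

    # -- parameter plumbing -------------------------------------------------

    def _layers(self):
        for blk in self.encoder:
            yield from (blk["conv"], blk["bn"])
        if self.bottleneck:
            yield from (self.bottleneck["conv"], self.bottleneck["bn"])
        for blk in self.decoder:
            yield from (blk["conv_up"], blk["bn_up"], blk["conv_merge"], blk["bn_merge"])
        yield from (self.project, self.cls_conv1, self.cls_conv2)

    def parameters(self):
        handles = []
        for layer in self._layers():
            handles.extend(layer.params())
        return handles

    def n_parameters(self) -> int:
        """Brute-force enumeration of trainable tensor sizes."""
        return sum(getattr(l, n).size for l, n in self.parameters())

    def zero_grad(self):
        for layer in self._layers():
            layer.zero_grad()

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.parameters(), lr=lr)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, i: int, train: bool = False):
        """Map a (B, C, L) signal batch to (B, K, L/i) segment logits.

        L must be a multiple of ``i``; odd intermediate lengths inside the
        encoder are handled by edge-replication padding before pooling.
        Also returns the (B, K, L) high-frequency score map.
        """
        x = np.ascontiguousarray(x, dtype=_nn.DTYPE)
        if x.ndim != 3 or x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected (B, {self.config.in_channels}, L) input, got {x.shape}")
        if x.shape[-1] % i:
            raise ValueError(f"input length {x.shape[-1]} is not a multiple of i={i}")
        h = x
        skip_lengths = []
        for blk in self.encoder:
            h = blk["bn"].forward(blk["elu"].forward(blk["conv"].forward(h)), train)
            blk["_skip"] = h
            skip_lengths.append(h.shape[-1])
            h = blk["pool"].forward(h)
        if self.bottleneck:
            b = self.bottleneck
            h = b["bn"].forward(b["elu"].forward(b["conv"].forward(h)), train)
        for d, blk in enumerate(self.decoder):
            skip = self.encoder[self.config.depth - 1 - d]["_skip"]
            h = blk["up"].forward(h)
            h = blk["crop"].forward(h, skip.shape[-1])
            h = blk["bn_up"].forward(blk["elu_up"].forward(blk["conv_up"].forward(h)), train)
            h = np.concatenate([h, skip], axis=1)
            h = blk["bn_merge"].forward(
                blk["elu_merge"].forward(blk["conv_merge"].forward(h)), train)
        score = self.project.forward(h)
        z = self.seg_pool.forward(score, i)
        z = self.cls_conv2.forward(self.cls_elu.forward(self.cls_conv1.forward(z)))
        self._score = score
        return z, score

    def backward(self, dz: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients from d(loss)/d(logits); returns
        the gradient with respect to the input signal."""
        d = self.cls_conv1.backward(self.cls_elu.backward(self.cls_conv2.backward(dz)))
        d = self.seg_pool.backward(d)
        d = self.project.backward(d)
        skip_grads: dict[int, np.ndarray] = {}
        for dd in range(len(self.decoder) - 1, -1, -1):
            blk = self.decoder[dd]
            d = blk["conv_merge"].backward(
                blk["elu_merge"].backward(blk["bn_merge"].backward(d)))
            f = self.decoder[dd]["bn_up"].gamma.shape[0]
            d, dskip = d[:, :f], d[:, f:]
            skip_grads[self.config.depth - 1 - dd] = dskip
            d = blk["conv_up"].backward(blk["elu_up"].backward(blk["bn_up"].backward(d)))
            d = blk["up"].backward(blk["crop"].backward(d))
        if self.bottleneck:
            b = self.bottleneck
            d = b["conv"].backward(b["elu"].backward(b["bn"].backward(d)))
        for e in range(len(self.encoder) - 1, -1, -1):
            blk = self.encoder[e]
            d = blk["pool"].backward(d)
            d = d + skip_grads[e]
            d = blk["conv"].backward(blk["elu"].backward(blk["bn"].backward(d)))
        return d

    def predict_proba(self, x: np.ndarray, i: int) -> np.ndarray:
        """Row-stochastic (B, T, K) posteriors in evaluation mode."""
        z, _ = self.forward(x, i, train=False)
        return np.transpose(softmax(z.astype(np.float64), axis=1), (0, 2, 1))

    # -- checkpointing ------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for k, (layer, name) in enumerate(self.parameters()):
            state[f"p{k:03d}_{name}"] = getattr(layer, name)
        for k, layer in enumerate(self._layers()):
            if isinstance(layer, BatchNorm1d):
                state[f"bn{k:03d}_mean"] = layer.running_mean
                state[f"bn{k:03d}_var"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for k, (layer, name) in enumerate(self.parameters()):
            setattr(layer, name, np.array(state[f"p{k:03d}_{name}"], dtype=np.float32))
        for k, layer in enumerate(self._layers()):
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = np.array(state[f"bn{k:03d}_mean"], dtype=np.float32)
                layer.running_var = np.array(state[f"bn{k:03d}_var"], dtype=np.float32)

    def save(self, path) -> None:
        cfg = json.dumps(asdict(self.config))
        np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
                 **self.state_arrays())

    @classmethod
    def load(cls, path) -> "USleepNet":
        with np.load(path) as z:
            cfg = json.loads(bytes(z["__config__"]).decode())
            model = cls(ModelConfig(**cfg))
            model.load_state_arrays({k: z[k] for k in z.files if k != "__config__"})
        return model


def build_model(config: ModelConfig | None = None, seed: int = 0) -> USleepNet:
    """Construct the network with randomly initialized weights."""
    return USleepNet(config or ModelConfig(), seed=seed)
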