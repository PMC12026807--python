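"""The CRISPR-MFH network: dimensional-transform blocks, a multi-branch
grouped depthwise/pointwise convolution block, a channel-spatial hybrid
attention block, and an MLP classification head.

Each encoded matrix is treated as a single-channel 2-D grid of height L
(sequence position) and width 7 (feature channel grid); the two 5-wide
one-hot matrices are zero-padded to width 7 so that the square kernels of
the convolutional blocks apply uniformly.

Data flow::

    sgRNA (L x 5) --DT--+
    DNA   (L x 5) --DT--+--concat(3F)--gDP--CSAM--flatten--MLP--softmax(2)
    fused (L x 7) --DT--+

The gDP block runs four parallel depthwise-separable branches with kernel
sizes 1, 3, 5 and 7, each emitting C/4 channels, concatenates them back to
C channels and adds the input (residual). The CSAM block reweights the gDP
output by channel attention (shared MLP over global average- and
max-pooled channel descriptors, Sigmoid) and by spatial attention (7 x 7
convolution over the channel-wise mean/max maps, Sigmoid), fuses the two
reweighted maps with a 1 x 1 convolution, and adds the input (residual).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .exceptions import ConfigurationError, DimensionError
from .nn import Tensor

#: Spatial width of the network's input grid (the fused-matrix width).
GRID_WIDTH = 7


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``dt_filters`` is the per-branch width of the dimensional-transform
    blocks; after concatenating the three branches the trunk carries
    ``3 * dt_filters`` channels, which must be divisible by the number of
    gDP kernel sizes.
    """

    dt_filters: int = 32
    dt_kernel: int = 3
    gdp_kernels: tuple[int, ...] = (1, 3, 5, 7)
    attention_reduction: int = 8
    mlp_sizes: tuple[int, ...] = (80, 20, 2)
    dropout: float = 0.35
    input_length: int = 23
    fused_width: int = GRID_WIDTH
    encoding_mode: str = "onehot"  # "embedding" reserved, not implemented

    def __post_init__(self):
        if (3 * self.dt_filters) % len(self.gdp_kernels) != 0:
            raise ConfigurationError(
                f"3*dt_filters ({3 * self.dt_filters}) must be divisible by "
                f"the number of gDP kernels ({len(self.gdp_kernels)})"
            )
        if self.mlp_sizes[-1] != 2:
            raise ConfigurationError("mlp_sizes must end in 2 (binary softmax)")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must lie in [0, 1)")
        if self.encoding_mode != "onehot":
            raise ConfigurationError(
                f"encoding_mode {self.encoding_mode!r} is reserved; only "
                "'onehot' is implemented"
            )

    @property
    def trunk_channels(self) -> int:
        return 3 * self.dt_filters

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gdp_kernels"] = list(self.gdp_kernels)
        d["mlp_sizes"] = list(self.mlp_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["gdp_kernels"] = tuple(d.get("gdp_kernels", (1, 3, 5, 7)))
        d["mlp_sizes"] = tuple(d.get("mlp_sizes", (80, 20, 2)))
        return cls(**d)


def pad_to_grid(matrices: np.ndarray) -> np.ndarray:
    """Zero-pad a batch of L x W matrices (W <= 7) to the L x 7 grid."""
    arr = np.asarray(matrices, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    width = arr.shape[2]
    if width > GRID_WIDTH:
        raise DimensionError(f"matrix width {width} exceeds grid width {GRID_WIDTH}")
    if width < GRID_WIDTH:
        arr = np.pad(arr, ((0, 0), (0, 0), (0, GRID_WIDTH - width)))
    return arr


class DTBlock(nn.Layer):
    """Dimensional transform: convolution -> batch norm -> ReLU.

    Aligns each input matrix to a common L x 7 x F feature map while
    extracting local base-combination patterns.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.conv = nn.Conv2d(1, config.dt_filters, config.dt_kernel, rng)
        self.bn = nn.BatchNorm2d(config.dt_filters)

    def __call__(self, matrices, training: bool = False) -> Tensor:
        if isinstance(matrices, Tensor):
            x = matrices
        else:
            x = Tensor(pad_to_grid(matrices)[..., None])  # N, L, 7, 1
        return nn.relu(self.bn(self.conv(x), training=training))


class GDPBlock(nn.Layer):
    """Grouped depthwise+pointwise multi-branch block with a residual add.

    Each branch applies a k x k depthwise convolution followed by a 1 x 1
    pointwise convolution emitting C/len(kernels) channels; branch outputs
    are concatenated back to C channels and summed with the input.
    """

    def __init__(self, channels: int, kernels: tuple[int, ...],
                 rng: np.random.Generator):
        if channels % len(kernels) != 0:
            raise ConfigurationError(
                f"channel count {channels} not divisible by {len(kernels)} branches"
            )
        branch_out = channels // len(kernels)
        self.depthwise = [nn.DepthwiseConv2d(channels, k, rng) for k in kernels]
        self.pointwise = [nn.Conv2d(channels, branch_out, 1, rng) for _ in kernels]

    def __call__(self, x: Tensor) -> Tensor:
        branches = [pw(nn.depthwise_conv2d(x, dw.weight))
                    for dw, pw in zip(self.depthwise, self.pointwise)]
        return nn.add(x, nn.concatenate(branches, axis=3))


class ChannelAttention(nn.Layer):
    """Sigmoid channel weights from a shared MLP over GAP and GMP descriptors."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        if channels < reduction:
            raise ConfigurationError(
                f"channels ({channels}) must be >= reduction ratio ({reduction})"
            )
        hidden = max(1, channels // reduction)
        self.fc1 = nn.Dense(channels, hidden, rng)
        self.fc2 = nn.Dense(hidden, channels, rng)

    def _mlp(self, descriptor: Tensor) -> Tensor:
        return self.fc2(nn.relu(self.fc1(descriptor)))

    def __call__(self, x: Tensor) -> Tensor:
        gap = nn.mean(x, axis=(1, 2))  # N x C
        gmp = nn.amax(x, axis=(1, 2))  # N x C
        weights = nn.sigmoid(nn.add(self._mlp(gap), self._mlp(gmp)))
        return nn.reshape(weights, (x.shape[0], 1, 1, x.shape[3]))


class SpatialAttention(nn.Layer):
    """Sigmoid spatial map from a 7x7 convolution over channel mean/max maps."""

    def __init__(self, rng: np.random.Generator, kernel_size: int = 7):
        self.conv = nn.Conv2d(2, 1, kernel_size, rng)

    def __call__(self, x: Tensor) -> Tensor:
        avg_map = nn.mean(x, axis=(3,), keepdims=True)
        max_map = nn.amax(x, axis=(3,), keepdims=True)
        return nn.sigmoid(self.conv(nn.concatenate([avg_map, max_map], axis=3)))


class CSAMBlock(nn.Layer):
    """Channel-spatial hybrid attention with residual fusion.

    ``out = x + Conv1x1([CA(x) * x ; SA(x) * x])``.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        self.channel_attention = ChannelAttention(channels, reduction, rng)
        self.spatial_attention = SpatialAttention(rng)
        self.fuse = nn.Conv2d(2 * channels, channels, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        ca = nn.mul(self.channel_attention(x), x)
        sa = nn.mul(self.spatial_attention(x), x)
        return nn.add(x, self.fuse(nn.concatenate([ca, sa], axis=3)))


class CrisprMFH(nn.Layer):
    """The full off-target classifier."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.dt_sgrna = DTBlock(config, rng)
        self.dt_dna = DTBlock(config, rng)
        self.dt_fused = DTBlock(config, rng)
        channels = config.trunk_channels
        self.gdp = GDPBlock(channels, config.gdp_kernels, rng)
        self.csam = CSAMBlock(channels, config.attention_reduction, rng)
        flat = config.input_length * GRID_WIDTH * channels
        sizes = (flat,) + tuple(config.mlp_sizes)
        self.mlp = [nn.Dense(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self._dropout_rng = np.random.default_rng(seed + 1)

    def forward(self, sgrna: np.ndarray, dna: np.ndarray, fused: np.ndarray,
                training: bool = False) -> Tensor:
        """Logits (N x 2) for a batch of encoded triples."""
        parts = [
            self.dt_sgrna(sgrna, training=training),
            self.dt_dna(dna, training=training),
            self.dt_fused(fused, training=training),
        ]
        x = nn.concatenate(parts, axis=3)
        x = self.gdp(x)
        x = self.csam(x)
        n = x.shape[0]
        x = nn.reshape(x, (n, -1))
        rate = self.config.dropout
        for layer in self.mlp[:-1]:
            x = nn.relu(layer(x))
            x = nn.dropout(x, rate, self._dropout_rng, training)
        return self.mlp[-1](x)

    def predict_proba(self, sgrna, dna, fused, batch_size: int = 512) -> np.ndarray:
        """Softmax class probabilities (N x 2), deterministic (no dropout)."""
        outputs = []
        n = len(sgrna)
        for start in range(0, n, batch_size):
            sl = slice(start, start + batch_size)
            logits = self.forward(sgrna[sl], dna[sl], fused[sl], training=False)
            outputs.append(nn.softmax(logits.data))
        return np.concatenate(outputs, axis=0)

    def score_pairs(self, pairs, batch_size: int = 512) -> np.ndarray:
        """Positive-class probability for an iterable of GuideTargetPair."""
        from .encoding import encode_dataset

        sg, dn, fu, _ = encode_dataset(list(pairs))
        return self.predict_proba(sg, dn, fu, batch_size=batch_size)[:, 1]

    # -- (de)serialization ---------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        for name, bn in (("sg", self.dt_sgrna.bn), ("dna", self.dt_dna.bn),
                         ("fused", self.dt_fused.bn)):
            state[f"bn_{name}_mean"] = bn.running_mean
            state[f"bn_{name}_var"] = bn.running_var
        return state

    def save(self, path) -> Path:
        """Write weights (.npz) plus a JSON config sidecar."""
        path = Path(path)
        np.savez_compressed(path, **self.state_arrays())
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(self.config.to_dict(), indent=2))
        return path

    @classmethod
    def load(cls, path) -> "CrisprMFH":
        path = Path(path)
        config = ModelConfig.from_dict(json.loads(path.with_suffix(".json").read_text()))
        model = cls(config)
        with np.load(path if path.suffix else path.with_suffix(".npz")) as archive:
            for i, p in enumerate(model.parameters()):
                p.data = archive[f"param_{i}"].astype(np.float32)
            for name, bn in (("sg", model.dt_sgrna.bn), ("dna", model.dt_dna.bn),
                             ("fused", model.dt_fused.bn)):
                bn.running_mean = archive[f"bn_{name}_mean"]
                bn.running_var = archive[f"bn_{name}_var"]
        return model


def build_model(config: ModelConfig | None = None, seed: int = 0
                ) -> tuple[CrisprMFH, dict]:
    """Construct an untrained network and a parameter-count report."""
    config = config or ModelConfig()
    model = CrisprMFH(config, seed=seed)
    report = {
        "total_parameters": count_parameters(model),
        "trunk_channels": config.trunk_channels,
        "input_shape": [config.input_length, GRID_WIDTH],
    }
    return model, report


def count_parameters(model: nn.Layer) -> int:
    """Total number of trainable scalars in a network."""
    return int(sum(p.data.size for p in model.parameters()))
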