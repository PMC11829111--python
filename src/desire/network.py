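"""The DESIRE dose-prediction architecture.

Two progressive 3-D UNets:

* **UNet-1** — a 4-level encoder/decoder with plain convolution blocks for
  initial feature extraction.  Downsampling is by stride-2 convolution,
  upsampling by trilinear interpolation, decoder fusion by residual blocks.
* **UNet-2** — a 5-level network whose level widths double UNet-1's at every
  shared level.  Its encoder uses residual-dense (RD) blocks: a stride-2
  downsampling convolution feeding an upper branch of three densely
  concatenating convolution stages (global features) and a lower 1x1x1 branch
  (local features), fused by summation and a final 1x1x1 projection.  At each
  shared resolution the UNet-1 decoder feature is concatenated into the
  UNet-2 stream, and a squeeze-excitation channel-attention module derived
  from the UNet-1 decoder features gates the matching UNet-2 decoder
  channels.

Every convolution is followed by instance normalization and a ReLU except
the final linear 1x1x1 head (predictions may exceed 1.0 in normalized dose
units).  In training mode, four channel-dropout perturbations of the shared
penultimate feature map are pushed through the shared head in the same
forward pass, yielding the diverse outputs d1..d4 the difficult-region loss
consumes.  All weights are Kaiming-initialized from the config seed, so two
builds from one config are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import (Tensor, channel_dropout, concat, conv3d, global_avg_pool,
                       instance_norm, upsample_trilinear)
from .preprocess import ModelInput

__all__ = ["ModelConfig", "ForwardResult", "DesireNet", "build_model",
           "RDBlock", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 5
    base_channels_unet1: int = 16
    depth_unet1: int = 4
    depth_unet2: int = 5
    channel_multiplier_unet2: int = 2
    dropout_rates: Tuple[float, float, float, float] = (0.1, 0.2, 0.3, 0.4)
    rd_growth: int = 8
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if self.base_channels_unet1 < 2 or self.base_channels_unet1 % 2:
            raise ValueError("base_channels_unet1 must be an even integer >= 2")
        if self.depth_unet1 != 4 or self.depth_unet2 != 5:
            raise ValueError("the architecture is defined for depths 4 (UNet-1) "
                             "and 5 (UNet-2)")
        if self.channel_multiplier_unet2 != 2:
            raise ValueError("UNet-2 widths are twice UNet-1's; multiplier must be 2")
        rates = tuple(float(r) for r in self.dropout_rates)
        if len(rates) != 4 or any(not 0 < r < 1 for r in rates) \
                or any(b <= a for a, b in zip(rates, rates[1:])):
            raise ValueError("dropout_rates must be 4 strictly increasing values in (0,1)")
        if self.rd_growth < 2:
            raise ValueError("rd_growth must be >= 2")
        object.__setattr__(self, "dropout_rates", rates)

    def to_json(self) -> Dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_json(cls, d: Dict) -> "ModelConfig":
        d = dict(d)
        d["dropout_rates"] = tuple(d["dropout_rates"])
        return cls(**d)


@dataclass
class ForwardResult:
    """Network outputs: the dose map and, in training mode, d1..d4."""

    dose_pred: Tensor
    dropout_preds: Optional[List[Tensor]] = None
    attention_weights: Optional[List[np.ndarray]] = None


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Layer:
    def parameters(self) -> List[Tensor]:
        raise NotImplementedError


class ConvUnit(_Layer):
    """conv(k^3, optional stride) -> instance norm -> ReLU (bias-free conv)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 dtype: np.dtype, stride: int = 1, relu: bool = True):
        fan_in = cin * k ** 3
        self.w = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                   size=(cout, cin, k, k, k)).astype(dtype),
                        requires_grad=True)
        self.gain = Tensor(np.ones(cout, dtype=dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)
        self.stride = stride
        self.relu = relu

    def __call__(self, x: Tensor) -> Tensor:
        out = instance_norm(conv3d(x, self.w, stride=self.stride), self.gain, self.bias)
        return out.relu() if self.relu else out

    def parameters(self) -> List[Tensor]:
        return [self.w, self.gain, self.bias]


class PlainBlock(_Layer):
    """Two 3x3x3 ConvUnits — the standard UNet encoder block."""

    def __init__(self, cin: int, cout: int, rng, dtype):
        self.c1 = ConvUnit(cin, cout, 3, rng, dtype)
        self.c2 = ConvUnit(cout, cout, 3, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.c2(self.c1(x))

    def parameters(self) -> List[Tensor]:
        return self.c1.parameters() + self.c2.parameters()


class ResBlock(_Layer):
    """Residual fusion block for decoders: two 3^3 convs plus a 1^3 skip."""

    def __init__(self, cin: int, cout: int, rng, dtype):
        self.c1 = ConvUnit(cin, cout, 3, rng, dtype)
        self.c2 = ConvUnit(cout, cout, 3, rng, dtype, relu=False)
        self.skip = ConvUnit(cin, cout, 1, rng, dtype, relu=False)

    def __call__(self, x: Tensor) -> Tensor:
        return (self.c2(self.c1(x)) + self.skip(x)).relu()

    def parameters(self) -> List[Tensor]:
        return self.c1.parameters() + self.c2.parameters() + self.skip.parameters()


class RDBlock(_Layer):
    """Residual-dense block: stride-2 downsampling, dense upper branch (three
    concatenating stages of ``growth`` channels), 1x1x1 local lower branch,
    element-wise sum, final 1x1x1 projection."""

    N_STAGES = 3

    def __init__(self, cin: int, cout: int, growth: int, rng, dtype):
        self.down = ConvUnit(cin, cout, 3, rng, dtype, stride=2)
        self.stages = [ConvUnit(cout + s * growth, growth, 3, rng, dtype)
                       for s in range(self.N_STAGES)]
        self.upper_proj = ConvUnit(cout + self.N_STAGES * growth, cout, 1, rng, dtype)
        self.lower = ConvUnit(cout, cout, 1, rng, dtype)
        self.fuse = ConvUnit(cout, cout, 1, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        if any(d % 2 for d in x.shape[1:]):
            raise ValueError(f"RD block needs even spatial dims, got {x.shape[1:]}")
        h = self.down(x)
        dense = h
        for stage in self.stages:
            dense = concat([dense, stage(dense)], axis=0)
        return self.fuse(self.upper_proj(dense) + self.lower(h))

    def parameters(self) -> List[Tensor]:
        ps = self.down.parameters() + self.upper_proj.parameters() \
            + self.lower.parameters() + self.fuse.parameters()
        for s in self.stages:
            ps += s.parameters()
        return ps


class SEAttention(_Layer):
    """Squeeze-excitation channel attention: global average pool -> bottleneck
    1x1x1 conv -> ReLU -> expansion 1x1x1 conv -> sigmoid.  Bias-free, so an
    all-zero feature map always yields weights of exactly 0.5."""

    def __init__(self, cin: int, cout: int, rng, dtype, reduction: int = 4):
        hidden = max(cin // reduction, 1)
        self.w1 = Tensor(rng.normal(0.0, np.sqrt(2.0 / cin),
                                    size=(hidden, cin, 1, 1, 1)).astype(dtype),
                         requires_grad=True)
        self.w2 = Tensor(rng.normal(0.0, np.sqrt(2.0 / hidden),
                                    size=(cout, hidden, 1, 1, 1)).astype(dtype),
                         requires_grad=True)

    def __call__(self, features: Tensor) -> Tensor:
        pooled = global_avg_pool(features)
        return conv3d(conv3d(pooled, self.w1).relu(), self.w2).sigmoid()

    def parameters(self) -> List[Tensor]:
        return [self.w1, self.w2]


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class DesireNet:
    """Progressive dual-UNet dose predictor (see module docstring)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(config.seed)
        b = config.base_channels_unet1
        cin = config.in_channels
        g = config.rd_growth
        self.unet1_widths = (b, 2 * b, 4 * b, 8 * b)
        self.unet2_widths = (2 * b, 4 * b, 8 * b, 16 * b, 32 * b)

        # UNet-1 encoder
        self.e0 = PlainBlock(cin, b, rng, dtype)
        self.down0 = ConvUnit(b, 2 * b, 3, rng, dtype, stride=2)
        self.e1 = PlainBlock(2 * b, 2 * b, rng, dtype)
        self.down1 = ConvUnit(2 * b, 4 * b, 3, rng, dtype, stride=2)
        self.e2 = PlainBlock(4 * b, 4 * b, rng, dtype)
        self.down2 = ConvUnit(4 * b, 8 * b, 3, rng, dtype, stride=2)
        self.e3 = PlainBlock(8 * b, 8 * b, rng, dtype)
        # UNet-1 decoder (residual fusion after trilinear upsampling)
        self.d2 = ResBlock(8 * b + 4 * b, 4 * b, rng, dtype)
        self.d1 = ResBlock(4 * b + 2 * b, 2 * b, rng, dtype)
        self.d0 = ResBlock(2 * b + b, b, rng, dtype)

        # UNet-2 encoder: stem + RD blocks, with UNet-1 feature fusion
        self.stem = PlainBlock(cin + b, 2 * b, rng, dtype)
        self.rd1 = RDBlock(2 * b, 4 * b, g, rng, dtype)
        self.fuse1 = ConvUnit(4 * b + 2 * b, 4 * b, 1, rng, dtype)
        self.rd2 = RDBlock(4 * b, 8 * b, g, rng, dtype)
        self.fuse2 = ConvUnit(8 * b + 4 * b, 8 * b, 1, rng, dtype)
        self.rd3 = RDBlock(8 * b, 16 * b, g, rng, dtype)
        self.fuse3 = ConvUnit(16 * b + 8 * b, 16 * b, 1, rng, dtype)
        self.rd4 = RDBlock(16 * b, 32 * b, g, rng, dtype)
        # UNet-2 decoder with channel attention from UNet-1 decoder features
        self.u3 = ResBlock(32 * b + 16 * b, 16 * b, rng, dtype)
        self.u2 = ResBlock(16 * b + 8 * b, 8 * b, rng, dtype)
        self.u1 = ResBlock(8 * b + 4 * b, 4 * b, rng, dtype)
        self.u0 = ResBlock(4 * b + 2 * b, 2 * b, rng, dtype)
        self.attn = [SEAttention(w1, 2 * w1, rng, dtype) for w1 in self.unet1_widths]

        # shared linear head (the only biased, norm-free convolution)
        self.head_w = Tensor(rng.normal(0.0, np.sqrt(2.0 / (2 * b)),
                                        size=(1, 2 * b, 1, 1, 1)).astype(dtype),
                             requires_grad=True)
        self.head_b = Tensor(np.zeros(1, dtype=dtype), requires_grad=True)
        self._dtype = dtype

        self._layers: List[_Layer] = [
            self.e0, self.down0, self.e1, self.down1, self.e2, self.down2, self.e3,
            self.d2, self.d1, self.d0, self.stem, self.rd1, self.fuse1, self.rd2,
            self.fuse2, self.rd3, self.fuse3, self.rd4, self.u3, self.u2, self.u1,
            self.u0, *self.attn,
        ]

    # -- parameters ----------------------------------------------------------
    def parameters(self) -> List[Tensor]:
        ps: List[Tensor] = []
        for layer in self._layers:
            ps += layer.parameters()
        ps += [self.head_w, self.head_b]
        return ps

    @property
    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- pieces exposed for inspection --------------------------------------
    def channel_attention(self, unet1_features: Sequence[Tensor]) -> List[Tensor]:
        """Per-level attention weight vectors (shape (2*w1, 1, 1, 1), in (0,1))."""
        if len(unet1_features) != 4:
            raise ValueError(f"channel attention expects 4 level features, "
                             f"got {len(unet1_features)}")
        return [att(f) for att, f in zip(self.attn, unet1_features)]

    def _head(self, features: Tensor) -> Tensor:
        out = conv3d(features, self.head_w, bias=self.head_b)
        return out.reshape(*out.shape[1:])

    # -- forward -------------------------------------------------------------
    def forward(self, model_input: ModelInput | np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None,
                return_attention: bool = False) -> ForwardResult:
        x_np = model_input.channels if isinstance(model_input, ModelInput) else model_input
        x_np = np.asarray(x_np, dtype=self._dtype)
        if x_np.ndim != 4 or x_np.shape[0] != self.config.in_channels:
            raise ValueError(f"input must be ({self.config.in_channels}, Z, Y, X), "
                             f"got {x_np.shape}")
        divisor = 2 ** (self.config.depth_unet2 - 1)
        if any(d % divisor for d in x_np.shape[1:]):
            raise ValueError(f"spatial dims {x_np.shape[1:]} must be divisible by "
                             f"{divisor} (no silent padding)")
        if training and rng is None:
            rng = np.random.default_rng(self.config.seed)

        x = Tensor(x_np)

        # UNet-1
        f_e0 = self.e0(x)
        f_e1 = self.e1(self.down0(f_e0))
        f_e2 = self.e2(self.down1(f_e1))
        f_e3 = self.e3(self.down2(f_e2))
        f_d2 = self.d2(concat([upsample_trilinear(f_e3, f_e2.shape[1:]), f_e2]))
        f_d1 = self.d1(concat([upsample_trilinear(f_d2, f_e1.shape[1:]), f_e1]))
        f_d0 = self.d0(concat([upsample_trilinear(f_d1, f_e0.shape[1:]), f_e0]))
        unet1_feats = [f_d0, f_d1, f_d2, f_e3]  # full, /2, /4, /8

        attn_weights = self.channel_attention(unet1_feats)

        # UNet-2 encoder
        g0 = self.stem(concat([x, f_d0]))
        g1 = self.fuse1(concat([self.rd1(g0), f_d1]))
        g2 = self.fuse2(concat([self.rd2(g1), f_d2]))
        g3 = self.fuse3(concat([self.rd3(g2), f_e3]))
        g4 = self.rd4(g3)

        # UNet-2 decoder, attention-gated
        h = self.u3(concat([upsample_trilinear(g4, g3.shape[1:]), g3])) * attn_weights[3]
        h = self.u2(concat([upsample_trilinear(h, g2.shape[1:]), g2])) * attn_weights[2]
        h = self.u1(concat([upsample_trilinear(h, g1.shape[1:]), g1])) * attn_weights[1]
        penult = self.u0(concat([upsample_trilinear(h, g0.shape[1:]), g0])) * attn_weights[0]

        dose_pred = self._head(penult)
        dropout_preds = None
        if training:
            dropout_preds = [self._head(channel_dropout(penult, rate, rng))
                             for rate in self.config.dropout_rates]
        return ForwardResult(
            dose_pred=dose_pred,
            dropout_preds=dropout_preds,
            attention_weights=[np.asarray(w.data).ravel() for w in attn_weights]
            if return_attention else None,
        )

    __call__ = forward


def build_model(config: ModelConfig) -> DesireNet:
    """Construct a Kaiming-initialized DESIRE network from its config."""
    return DesireNet(config)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: DesireNet, path: str | Path) -> None:
    path = Path(path)
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez_compressed(path, config=json.dumps(model.config.to_json()), **arrays)


def load_checkpoint(path: str | Path) -> DesireNet:
    with np.load(Path(path), allow_pickle=False) as npz:
        config = ModelConfig.from_json(json.loads(str(npz["config"])))
        model = DesireNet(config)
        for i, p in enumerate(model.parameters()):
            p.data = npz[f"p{i}"].astype(p.data.dtype)
    return model
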