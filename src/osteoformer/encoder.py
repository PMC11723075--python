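"""Hierarchical transformer encoder with a configurable resolution schedule.

Four sequential stages, each an overlapped patch embedding followed by
transformer blocks.  Every block pairs spatially-reduced (efficient)
multi-head self-attention with a Mix-FFN whose 3x3 depthwise convolution
stack has configurable depth M: M = 1 is the standard SegFormer Mix-FFN,
and raising M deepens the convolutional pathway that supplies positional
information — the "data-efficient" modification, together with running the
first stage at (up to) full input resolution instead of quarter resolution.

Resolution is controlled by ``ModelConfig.stage_fractions``: stage i emits
feature maps of side ``input_side * fraction[i]``.  Fractions above 1
bilinearly upsample the input before embedding (the 512 x 512 ablation row).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .config import ConfigurationError, ModelConfig
from .nn import (
    Conv2d,
    LayerNorm,
    Linear,
    Module,
    Tensor,
    bilinear_resize,
    gelu,
    softmax,
)

__all__ = [
    "FeaturePyramid",
    "HierarchicalEncoder",
    "EfficientSelfAttention",
    "MixFFN",
    "TransformerBlock",
    "OverlapPatchEmbed",
    "encode",
    "count_parameters",
]


def count_parameters(module: Module) -> int:
    return int(sum(p.data.size for p in module.parameters()))


def tokens_from_map(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, H*W, C)"""
    B, C, H, W = x.shape
    return x.transpose(0, 2, 3, 1).reshape(B, H * W, C)


def map_from_tokens(x: Tensor, H: int, W: int) -> Tensor:
    """(B, H*W, C) -> (B, C, H, W)"""
    B, _, C = x.shape
    return x.reshape(B, H, W, C).transpose(0, 3, 1, 2)


@dataclass
class FeaturePyramid:
    """The four per-stage feature maps, finest (largest side) first."""

    levels: list[np.ndarray]  # each (C_i, H_i, W_i)

    def __post_init__(self):
        if len(self.levels) != 4:
            raise ValueError(f"a feature pyramid has exactly 4 levels, got {len(self.levels)}")
        sides = self.sides
        if any(a <= b for a, b in zip(sides, sides[1:])):
            raise ValueError(f"pyramid sides must strictly decrease, got {sides}")
        for lv in self.levels:
            if not np.isfinite(lv).all():
                raise ValueError("non-finite values in feature pyramid")

    @property
    def sides(self) -> tuple[int, ...]:
        return tuple(lv.shape[-1] for lv in self.levels)

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(lv.shape[0] for lv in self.levels)


class OverlapPatchEmbed(Module):
    """Strided overlapping convolution embedding, with layer-norm on tokens.

    ``scale`` is the resolution change entering the stage: integer > 1 means
    a strided downsampling embed (stride 4 uses a 7x7 kernel, as in the
    original first stage; stride 2 a 3x3); scale 1 keeps the side with a
    stride-1 3x3; a fractional scale < 1 upsamples bilinearly then embeds at
    stride 1.
    """

    def __init__(self, in_ch: int, out_ch: int, scale: Fraction, rng):
        if scale >= 1:
            if scale.denominator != 1:
                raise ConfigurationError(f"non-integer embed stride {scale}")
            stride = int(scale)
            kernel = 7 if stride == 4 else 3
            self.upsample = 1
        else:
            stride, kernel = 1, 3
            self.upsample = int(1 / scale)
        self.proj = Conv2d(in_ch, out_ch, kernel, rng, stride=stride,
                           padding=kernel // 2)
        self.norm = LayerNorm(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        if self.upsample > 1:
            x = bilinear_resize(x, x.shape[-1] * self.upsample)
        x = self.proj(x)
        B, C, H, W = x.shape
        return map_from_tokens(self.norm(tokens_from_map(x)), H, W)


class EfficientSelfAttention(Module):
    """Multi-head self-attention with spatial reduction of keys/values.

    With reduction r, keys and values are computed from the token grid
    downsampled r-fold by a learned r x r strided convolution, cutting the
    attention cost from O(N^2) to O(N^2 / r^2).  r = 1 is full attention.
    """

    def __init__(self, dim: int, heads: int, reduction: int, rng):
        if dim % heads:
            raise ConfigurationError(f"dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.reduction = reduction
        self.scale = (dim // heads) ** -0.5
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.proj = Linear(dim, dim, rng)
        if reduction > 1:
            self.sr = Conv2d(dim, dim, reduction, rng, stride=reduction)
            self.sr_norm = LayerNorm(dim)

    def _split_heads(self, t: Tensor) -> Tensor:
        B, N, C = t.shape
        return t.reshape(B, N, self.heads, C // self.heads).transpose(0, 2, 1, 3)

    def attention_weights(self, x: Tensor, H: int, W: int) -> Tensor:
        """The row-stochastic (B, heads, N, N') attention matrix."""
        q = self._split_heads(self.q(x)) * self.scale
        kv = x
        if self.reduction > 1:
            kv = tokens_from_map(self.sr(map_from_tokens(x, H, W)))
            kv = self.sr_norm(kv)
        k = self._split_heads(self.k(kv))
        return softmax(q @ k.transpose(0, 1, 3, 2), axis=-1), kv

    def forward(self, x: Tensor, H: int, W: int) -> Tensor:
        attn, kv = self.attention_weights(x, H, W)
        v = self._split_heads(self.v(kv))
        out = attn @ v  # (B, h, N, d)
        B, h, N, d = out.shape
        out = out.transpose(0, 2, 1, 3).reshape(B, N, h * d)
        return self.proj(out)


class MixFFN(Module):
    """Feed-forward sublayer with an M-deep 3x3 depthwise convolution stack.

    expand (linear) -> [3x3 depthwise conv -> GELU] x M -> project (linear).
    M = 1 reproduces the baseline Mix-FFN; larger M deepens the stack at the
    expanded width without residuals between the added layers.
    """

    def __init__(self, dim: int, expansion: int, conv_layers: int, rng):
        if not 1 <= conv_layers <= 5:
            raise ConfigurationError(
                f"Mix-FFN conv depth must be in [1, 5], got {conv_layers}")
        hidden = dim * expansion
        self.fc1 = Linear(dim, hidden, rng)
        self.convs = [Conv2d(hidden, hidden, 3, rng, padding=1, groups=hidden)
                      for _ in range(conv_layers)]
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor, H: int, W: int) -> Tensor:
        x = self.fc1(x)
        B, N, C = x.shape
        m = map_from_tokens(x, H, W)
        for conv in self.convs:
            m = gelu(conv(m))
        return self.fc2(tokens_from_map(m))


class TransformerBlock(Module):
    """Pre-norm residual pair: efficient attention then Mix-FFN."""

    def __init__(self, dim: int, heads: int, reduction: int,
                 conv_layers: int, expansion: int, rng):
        self.norm1 = LayerNorm(dim)
        self.attn = EfficientSelfAttention(dim, heads, reduction, rng)
        self.norm2 = LayerNorm(dim)
        self.ffn = MixFFN(dim, expansion, conv_layers, rng)

    def forward(self, x: Tensor, H: int, W: int) -> Tensor:
        x = x + self.attn(self.norm1(x), H, W)
        x = x + self.ffn(self.norm2(x), H, W)
        return x


class _Stage(Module):
    def __init__(self, in_ch: int, out_ch: int, scale: Fraction, depth: int,
                 heads: int, reduction: int, conv_layers: int, expansion: int, rng):
        self.embed = OverlapPatchEmbed(in_ch, out_ch, scale, rng)
        self.blocks = [TransformerBlock(out_ch, heads, reduction, conv_layers,
                                        expansion, rng) for _ in range(depth)]
        self.norm = LayerNorm(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        x = self.embed(x)
        B, C, H, W = x.shape
        t = tokens_from_map(x)
        for blk in self.blocks:
            t = blk(t, H, W)
        return map_from_tokens(self.norm(t), H, W)


class HierarchicalEncoder(Module):
    """Four-stage encoder mapping (B, 1, S, S) to a 4-level feature pyramid."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        scales = config.stage_scales()
        in_chs = (1,) + tuple(config.stage_channels[:3])
        self.stages = [
            _Stage(in_chs[i], config.stage_channels[i], scales[i],
                   config.stage_depths[i], config.stage_heads[i],
                   config.attention_reduction[i], config.mixffn_conv_layers,
                   config.mixffn_expansion, rng)
            for i in range(4)
        ]

    def forward(self, x: Tensor) -> list[Tensor]:
        B, C, H, W = x.shape
        if H != W:
            raise ConfigurationError(f"input must be square, got {H}x{W}")
        self.config.stage_sides(H)  # raises naming the offending stage
        out = []
        for stage in self.stages:
            x = stage(x)
            out.append(x)
        return out


def encode(image: np.ndarray, config: ModelConfig, seed: int = 0) -> FeaturePyramid:
    """Run a freshly initialised encoder on one (1, S, S) image."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 3 or img.shape[0] != 1:
        raise ValueError(f"expected a (1, S, S) image, got shape {img.shape}")
    enc = HierarchicalEncoder(config, np.random.default_rng(seed))
    levels = enc(Tensor(img[None]))
    return FeaturePyramid([lv.data[0].copy() for lv in levels])
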