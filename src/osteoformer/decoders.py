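"""Decoder heads: the All-MLP baseline and the FPN decoder with attention.

The All-MLP head linearly projects every pyramid level to a shared width,
upsamples all of them to the finest level's grid, concatenates, fuses with
a linear layer and predicts per-pixel class logits.

The FPN head walks the pyramid top-down: the coarsest level is processed by
a 3x3 convolution and (optionally) spatially-reduced self-attention; at each
finer level the running map is bilinearly upsampled and added to that
level's 3x3-convolved lateral projection, and the combined map again passes
through self-attention.  Disabling ``decoder_attention`` keeps the conv /
fusion path but removes every attention block (the "without attention"
ablation).  Both heads finish with a class projection and a bilinear
upsample to the input image grid.
"""

from __future__ import annotations

import numpy as np

from .config import ConfigurationError, ModelConfig
from .encoder import (
    EfficientSelfAttention,
    FeaturePyramid,
    map_from_tokens,
    tokens_from_map,
)
from .nn import (
    Conv2d,
    LayerNorm,
    Linear,
    Module,
    Tensor,
    bilinear_resize,
    concat,
    gelu,
)

__all__ = ["AllMLPDecoder", "FPNAttentionDecoder", "build_decoder",
           "allmlp_decode", "fpn_attention_decode"]


def _check_pyramid(levels) -> None:
    if len(levels) != 4:
        raise ValueError(f"decoder expects a 4-level pyramid, got {len(levels)}")
    sides = [lv.shape[-1] for lv in levels]
    if any(a <= b for a, b in zip(sides, sides[1:])):
        raise ValueError(f"pyramid sides must strictly decrease, got {sides}")


class AllMLPDecoder(Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        w = config.decoder_width
        self.linears = [Linear(c, w, rng) for c in config.stage_channels]
        self.fuse = Linear(4 * w, w, rng)
        self.classify = Linear(w, config.num_classes, rng)

    def forward(self, levels: list[Tensor], out_side: int) -> Tensor:
        _check_pyramid(levels)
        top = levels[0].shape[-1]
        ups = []
        for lv, lin in zip(levels, self.linears):
            B, C, H, W = lv.shape
            proj = map_from_tokens(lin(tokens_from_map(lv)), H, W)
            ups.append(bilinear_resize(proj, top))
        x = concat(ups, axis=1)
        B, C, H, W = x.shape
        t = gelu(self.fuse(tokens_from_map(x)))
        logits = map_from_tokens(self.classify(t), H, W)
        return bilinear_resize(logits, out_side)


class _ResidualAttention(Module):
    """Pre-norm residual spatially-reduced self-attention over a map."""

    def __init__(self, dim: int, heads: int, reduction: int, rng):
        self.norm = LayerNorm(dim)
        self.attn = EfficientSelfAttention(dim, heads, reduction, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        t = tokens_from_map(x)
        t = t + self.attn(self.norm(t), H, W)
        return map_from_tokens(t, H, W)


class FPNAttentionDecoder(Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        w = config.decoder_width
        self.attention_enabled = config.decoder_attention
        self.laterals = [Conv2d(c, w, 1, rng) for c in config.stage_channels]
        self.convs = [Conv2d(w, w, 3, rng, padding=1) for _ in range(4)]
        if self.attention_enabled:
            heads = 4 if w % 4 == 0 else 1
            self.attns = [_ResidualAttention(w, heads, r, rng)
                          for r in config.attention_reduction]
        # small head init keeps initial logits near zero
        self.classify = Conv2d(w, config.num_classes, 1, rng, std=0.02)

    def forward(self, levels: list[Tensor], out_side: int) -> Tensor:
        _check_pyramid(levels)
        x = None
        for i in range(3, -1, -1):  # coarsest -> finest
            lateral = self.convs[i](self.laterals[i](levels[i]))
            if x is None:
                x = lateral
            else:
                x = bilinear_resize(x, lateral.shape[-1]) + lateral
            if self.attention_enabled:
                x = self.attns[i](x)
        return bilinear_resize(self.classify(x), out_side)


def build_decoder(config: ModelConfig, rng: np.random.Generator) -> Module:
    if config.decoder_kind == "allmlp":
        return AllMLPDecoder(config, rng)
    if config.decoder_kind == "fpn":
        return FPNAttentionDecoder(config, rng)
    raise ConfigurationError(f"unknown decoder_kind {config.decoder_kind!r}")


def _decode(decoder: Module, pyramid: FeaturePyramid, out_side: int) -> np.ndarray:
    levels = [Tensor(lv[None].astype(np.float32)) for lv in pyramid.levels]
    return decoder(levels, out_side).data[0].copy()


def allmlp_decode(pyramid: FeaturePyramid, num_classes: int = 2,
                  out_side: int | None = None, decoder_width: int = 32,
                  seed: int = 0) -> np.ndarray:
    """Run a freshly initialised All-MLP head; returns (num_classes, S, S) logits."""
    cfg = ModelConfig(stage_channels=pyramid.channels, stage_heads=(1, 1, 1, 1),
                      decoder_kind="allmlp", decoder_attention=False,
                      num_classes=num_classes, decoder_width=decoder_width)
    dec = AllMLPDecoder(cfg, np.random.default_rng(seed))
    return _decode(dec, pyramid, out_side or pyramid.sides[0])


def fpn_attention_decode(pyramid: FeaturePyramid, num_classes: int = 2,
                         attention_enabled: bool = True,
                         out_side: int | None = None, decoder_width: int = 32,
                         seed: int = 0) -> np.ndarray:
    """Run a freshly initialised FPN head; returns (num_classes, S, S) logits."""
    cfg = ModelConfig(stage_channels=pyramid.channels, stage_heads=(1, 1, 1, 1),
                      decoder_kind="fpn", decoder_attention=attention_enabled,
                      num_classes=num_classes, decoder_width=decoder_width)
    dec = FPNAttentionDecoder(cfg, np.random.default_rng(seed))
    return _decode(dec, pyramid, out_side or pyramid.sides[0])
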