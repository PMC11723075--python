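"""Model and training configuration.

``ModelConfig`` captures every architecture degree of freedom the toolkit
ablates: the per-stage feature-map resolution schedule (as fractions of the
input side), the depth of the Mix-FFN convolution stack, channel widths,
attention heads and spatial-reduction ratios, and the decoder variant.

Four named presets cover the systems compared in the ablation studies:

* ``baseline``       — SegFormer: quarter-resolution first stage, Mix-FFN
                       with a single 3x3 convolution, All-MLP decoder.
* ``data_efficient`` — raised resolution schedule (full-resolution first
                       stage) and a deepened Mix-FFN convolution stack,
                       still with the All-MLP decoder.
* ``fpn``            — baseline encoder with the FPN-with-attention decoder.
* ``proposed``       — data-efficient encoder plus the FPN decoder.

Each preset has a ``tiny_*`` twin with small widths and depth 1 per stage,
sized for CPU-scale experiments and the test suite.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from fractions import Fraction

import yaml

#: proposed resolution schedule: feature sides 1, 1/2, 1/4, 1/8 of the input
PROPOSED_FRACTIONS = (1.0, 0.5, 0.25, 0.125)
#: baseline SegFormer schedule: 1/4, 1/8, 1/16, 1/32 of the input
BASELINE_FRACTIONS = (0.25, 0.125, 0.0625, 0.03125)


class ConfigurationError(ValueError):
    """Raised when a configuration violates an architectural constraint."""


@dataclass
class ModelConfig:
    stage_fractions: tuple[float, float, float, float] = PROPOSED_FRACTIONS
    mixffn_conv_layers: int = 2
    stage_channels: tuple[int, int, int, int] = (64, 128, 320, 512)
    stage_depths: tuple[int, int, int, int] = (3, 4, 18, 3)
    stage_heads: tuple[int, int, int, int] = (1, 2, 5, 8)
    attention_reduction: tuple[int, int, int, int] = (8, 4, 2, 1)
    decoder_kind: str = "fpn"
    decoder_attention: bool = True
    num_classes: int = 2
    mixffn_expansion: int = 4
    decoder_width: int = 128
    name: str = ""

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for f4 in (self.stage_fractions, self.stage_channels, self.stage_depths,
                   self.stage_heads, self.attention_reduction):
            if len(f4) != 4:
                raise ConfigurationError("all per-stage settings must have 4 entries")
        fr = self.stage_fractions
        if any(f <= 0 for f in fr) or any(a <= b for a, b in zip(fr, fr[1:])):
            raise ConfigurationError("stage_fractions must be positive and strictly decreasing")
        if not 1 <= self.mixffn_conv_layers <= 5:
            raise ConfigurationError(
                f"mixffn_conv_layers must be in [1, 5], got {self.mixffn_conv_layers}")
        for c, h in zip(self.stage_channels, self.stage_heads):
            if c % h:
                raise ConfigurationError(f"channels {c} not divisible by heads {h}")
        if any(r < 1 for r in self.attention_reduction):
            raise ConfigurationError("attention_reduction ratios must be >= 1")
        if self.decoder_kind not in ("allmlp", "fpn"):
            raise ConfigurationError(f"unknown decoder_kind {self.decoder_kind!r}")
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")

    # -- schedule arithmetic -------------------------------------------
    def stage_sides(self, input_side: int) -> tuple[int, ...]:
        """Feature-map side per stage; errors if the schedule does not divide."""
        sides = []
        for i, f in enumerate(self.stage_fractions):
            side = Fraction(input_side) * Fraction(f).limit_denominator(1 << 12)
            if side.denominator != 1:
                raise ConfigurationError(
                    f"input side {input_side} is not divisible by stage {i + 1} "
                    f"fraction {f}")
            sides.append(int(side))
        return tuple(sides)

    def stage_scales(self) -> tuple[Fraction, ...]:
        """Resolution change entering each stage relative to the previous one."""
        prev = Fraction(1)
        out = []
        for f in self.stage_fractions:
            cur = Fraction(f).limit_denominator(1 << 12)
            out.append(prev / cur)  # >1 means downsample by that stride
            prev = cur
        return tuple(out)

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("stage_fractions", "stage_channels", "stage_depths",
                  "stage_heads", "attention_reduction"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for k in ("stage_fractions", "stage_channels", "stage_depths",
                  "stage_heads", "attention_reduction"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def replace(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


_TINY = dict(stage_channels=(16, 32, 64, 128), stage_depths=(1, 1, 1, 1),
             stage_heads=(1, 2, 4, 8), decoder_width=32)

_PRESETS = {
    "baseline": dict(stage_fractions=BASELINE_FRACTIONS, mixffn_conv_layers=1,
                     decoder_kind="allmlp", decoder_attention=False),
    "data_efficient": dict(stage_fractions=PROPOSED_FRACTIONS, mixffn_conv_layers=2,
                           decoder_kind="allmlp", decoder_attention=False),
    "fpn": dict(stage_fractions=BASELINE_FRACTIONS, mixffn_conv_layers=1,
                decoder_kind="fpn", decoder_attention=True),
    "proposed": dict(stage_fractions=PROPOSED_FRACTIONS, mixffn_conv_layers=2,
                     decoder_kind="fpn", decoder_attention=True),
}


def preset(name: str, **overrides) -> ModelConfig:
    """Build a named configuration; ``tiny_<name>`` selects the small widths."""
    key = name
    extra: dict = {}
    if name.startswith("tiny_"):
        key = name[len("tiny_"):]
        extra = dict(_TINY)
    if key not in _PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from "
            f"{sorted(_PRESETS)} or their tiny_* variants")
    kw = {**_PRESETS[key], **extra, "name": name}
    kw.update(overrides)
    return ModelConfig(**kw)


@dataclass
class Hyperparams:
    """Training protocol: batch 4, 20 epochs, Adam at 1e-3, cross-entropy."""

    batch_size: int = 4
    epochs: int = 20
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    num_classes: int = 2
    seed: int = 0
    deterministic: bool = True

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ConfigurationError("only the adam optimizer is implemented")
        if self.loss != "cross_entropy":
            raise ConfigurationError("only the cross_entropy loss is implemented")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperparams":
        return cls(**d)
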