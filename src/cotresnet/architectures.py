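"""Assembly of full residual networks from block specifications.

Five architectures are provided: the two attention-augmented networks
(``cot_resnet18``, ``ccs_resnet50``) and the ablation baselines
(``resnet18``, ``resnet50``, ``resnet50_shuffle``).  All share the same
skeleton — a 7×7/stride-2 stem with 3×3/stride-2 max pooling, four stages of
residual blocks at widths 64/128/256/512 (scaled by an optional width
multiplier for desk-scale experiments), global average pooling and a fully
connected classifier head sized to the number of diagnostic classes.
Basic-block networks stack (2, 2, 2, 2) blocks per stage; bottleneck
networks stack (3, 4, 6, 3) with 4× channel expansion.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor, softmax
from .blocks import (
    BOTTLENECK_EXPANSION,
    BlockSpec,
    CoTConfig,
    build_block,
)
from .nn import BatchNorm2d, Conv2d, Linear, MaxPool2d, Module, ReLU, global_avg_pool

__all__ = [
    "ArchSpec",
    "ResidualNetwork",
    "build_model",
    "count_parameters",
    "stage_output_shapes",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT = "cotresnet-checkpoint-v1"

# name -> (block kind, blocks per stage, channel expansion)
_ARCHITECTURES: dict[str, tuple[str, tuple[int, ...], int]] = {
    "cot_resnet18": ("basic_cot", (2, 2, 2, 2), 1),
    "resnet18": ("plain_basic", (2, 2, 2, 2), 1),
    "ccs_resnet50": ("ccs_bottleneck", (3, 4, 6, 3), BOTTLENECK_EXPANSION),
    "resnet50": ("plain_bottleneck", (3, 4, 6, 3), BOTTLENECK_EXPANSION),
    "resnet50_shuffle": ("bottleneck_shuffle_only", (3, 4, 6, 3), BOTTLENECK_EXPANSION),
}

_BASE_WIDTHS = (64, 128, 256, 512)


@dataclass(frozen=True)
class ArchSpec:
    """Declarative description of a network.

    width_multiplier scales every stage width (and the stem); it exists so
    the full architectures can be exercised at desk scale and is not part of
    the reference configurations.
    """

    name: str
    in_channels: int = 1
    n_classes: int = 3
    groups: int = 4
    cot: CoTConfig = field(default_factory=CoTConfig)
    width_multiplier: float = 1.0

    def __post_init__(self):
        if self.name not in _ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.name!r}; choose from {sorted(_ARCHITECTURES)}"
            )
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        widths = self.stage_widths
        kind = self.block_kind
        if kind in ("ccs_bottleneck", "bottleneck_shuffle_only"):
            for wd in widths:
                if wd % self.groups or (wd * BOTTLENECK_EXPANSION) % self.groups:
                    raise ValueError(
                        f"stage width {wd} (multiplier {self.width_multiplier}) "
                        f"not divisible by groups g={self.groups}"
                    )
        if kind in ("basic_cot", "ccs_bottleneck"):
            for wd in widths:
                self.cot.validate_channels(wd)

    @property
    def block_kind(self) -> str:
        return _ARCHITECTURES[self.name][0]

    @property
    def stage_blocks(self) -> tuple[int, ...]:
        return _ARCHITECTURES[self.name][1]

    @property
    def expansion(self) -> int:
        return _ARCHITECTURES[self.name][2]

    @property
    def stage_widths(self) -> tuple[int, ...]:
        return tuple(max(1, round(w * self.width_multiplier)) for w in _BASE_WIDTHS)

    def block_specs(self) -> list[list[BlockSpec]]:
        """Per-stage lists of BlockSpecs implementing this architecture."""
        kind = self.block_kind
        uses_groups = kind in ("ccs_bottleneck", "bottleneck_shuffle_only")
        uses_cot = kind in ("basic_cot", "ccs_bottleneck")
        stages = []
        in_ch = self.stage_widths[0]  # stem output width
        for stage_idx, (n_blocks, width) in enumerate(zip(self.stage_blocks, self.stage_widths)):
            blocks = []
            for b in range(n_blocks):
                stride = 2 if (stage_idx > 0 and b == 0) else 1
                blocks.append(
                    BlockSpec(
                        kind=kind,
                        in_channels=in_ch,
                        mid_channels=width,
                        stride=stride,
                        groups=self.groups if uses_groups else 1,
                        cot=self.cot if uses_cot else None,
                    )
                )
                in_ch = blocks[-1].out_channels
            stages.append(blocks)
        return stages


class ResidualNetwork(Module):
    """Stem → four residual stages → global average pool → linear head."""

    def __init__(self, spec: ArchSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        stem_width = spec.stage_widths[0]
        self.stem_conv = Conv2d(spec.in_channels, stem_width, 7, stride=2, padding=3, rng=rng)
        self.stem_bn = BatchNorm2d(stem_width)
        self.stem_relu = ReLU()
        self.maxpool = MaxPool2d(3, stride=2, padding=1)
        stage_specs = spec.block_specs()
        self.stages = [[build_block(bs, rng=rng) for bs in stage] for stage in stage_specs]
        self.out_channels = stage_specs[-1][-1].out_channels
        self.fc = Linear(self.out_channels, spec.n_classes, rng=rng)

    def children(self):
        yield from super().children()
        for i, stage in enumerate(self.stages):
            for j, block in enumerate(stage):
                yield f"stages.{i}.{j}", block

    def features(self, x: Tensor) -> list[Tensor]:
        """Per-stage feature maps (stem output first, then the four stages)."""
        x = Tensor._coerce(x)
        y = self.stem_relu(self.stem_bn(self.stem_conv(x)))
        outputs = [y]
        y = self.maxpool(y)
        for stage in self.stages:
            for block in stage:
                y = block(y)
            outputs.append(y)
        return outputs

    def forward(self, x: Tensor) -> Tensor:
        y = self.features(x)[-1]
        return self.fc(global_avg_pool(y))

    def predict_proba(self, x) -> np.ndarray:
        """Softmax class probabilities (inference mode)."""
        was_training = self.training
        self.eval()
        try:
            probs = softmax(self.forward(Tensor._coerce(x)), axis=1).data
        finally:
            if was_training:
                self.train()
        return probs

    def predict(self, x) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


def build_model(spec: ArchSpec, seed: int = 0) -> ResidualNetwork:
    """Build a seeded, randomly initialised network from its spec."""
    return ResidualNetwork(spec, seed=seed)


def count_parameters(model: Module) -> int:
    """Exact count of trainable scalars."""
    return int(sum(p.data.size for p in model.parameters()))


def stage_output_shapes(spec: ArchSpec, input_hw: tuple[int, int]) -> list[tuple[int, int, int]]:
    """Symbolic (C, H, W) after the stem conv and after each stage.

    For a 224×224 input the spatial sizes are 112 (stem), then 56/28/14/7.
    """

    def down(x: int) -> int:  # k-odd stride-2 same-padding arithmetic
        return (x - 1) // 2 + 1

    h, w = input_hw
    h, w = down(h), down(w)  # 7×7 stride-2 stem conv, padding 3
    shapes = [(spec.stage_widths[0], h, w)]
    h, w = down(h), down(w)  # 3×3 stride-2 max pool, padding 1
    for i, width in enumerate(spec.stage_widths):
        if i > 0:
            h, w = down(h), down(w)
        shapes.append((width * spec.expansion, h, w))
    return shapes


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: ResidualNetwork, path) -> None:
    """Single-file checkpoint: versioned header with the ArchSpec + weights."""
    header = {
        "format": CHECKPOINT_FORMAT,
        "spec": asdict(model.spec),
    }
    state = model.state_arrays()
    with open(path, "wb") as fh:  # explicit handle: keep the exact filename
        np.savez(
            fh,
            __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
            **state,
        )


def load_checkpoint(path) -> ResidualNetwork:
    with np.load(path) as archive:
        header = json.loads(bytes(archive["__header__"]).decode())
        if header.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"not a recognised checkpoint: {header.get('format')!r}")
        spec_dict = header["spec"]
        spec_dict["cot"] = CoTConfig(**spec_dict["cot"])
        spec = ArchSpec(**spec_dict)
        model = build_model(spec)
        model.load_state({k: archive[k] for k in archive.files if k != "__header__"})
    return model
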