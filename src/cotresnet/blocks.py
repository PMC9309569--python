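"""Building blocks for attention-augmented residual networks.

Three primitives are combined here:

* **Channel shuffle** — the deterministic interleaving permutation that lets
  grouped convolutions exchange information across groups (reshape to
  (g, C/g), transpose, flatten).
* **Grouped pointwise convolution** — 1×1 convolution whose channels are
  partitioned into ``g`` independent groups, cutting the weight count by a
  factor of ``g`` (see :class:`cotresnet.nn.Conv2d` with ``groups=g``).
* **CoT (Contextual Transformer) block** — a drop-in replacement for a 3×3
  convolution.  A k×k convolution of the input produces a *static context*
  map K¹; attention logits are computed from the channel-concatenation of K¹
  and the query (the raw input) by two successive 1×1 convolutions; the
  *dynamic context* K² aggregates a pointwise value embedding of the input
  over each position's k×k neighborhood using those attention weights
  (normalised so the k² weights at each position sum to one); the output is
  the elementwise fusion Y = K¹ + K².  Input and output shapes are identical,
  which is what lets the block replace a convolution inside a residual block.

From these, two residual block variants are assembled: the *basic CoT block*
(3×3 conv → CoT, plus skip) used in CoT-ResNet-18, and the *CCS bottleneck*
(grouped 1×1 → shuffle → CoT → grouped 1×1, plus skip) used in CCS-ResNet-50,
alongside the plain ResNet blocks they are ablated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, softmax, unfold_nbhd
from .nn import AvgPool2d, BatchNorm2d, Conv2d, Identity, Module, ReLU, Sequential

__all__ = [
    "CoTConfig",
    "ShuffleConfig",
    "BlockSpec",
    "channel_shuffle",
    "shuffle_permutation",
    "CoT",
    "BasicCoTBlock",
    "PlainBasicBlock",
    "CCSBottleneck",
    "PlainBottleneck",
    "ShuffleBottleneck",
    "build_block",
    "BOTTLENECK_EXPANSION",
]

BOTTLENECK_EXPANSION = 4


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoTConfig:
    """Hyperparameters of the contextual-transformer block.

    kernel: context kernel size k (odd); the static branch convolves with a
        k×k kernel and the dynamic branch attends over k² neighbors.
    reduction: bottleneck factor r of the two-layer attention embedding
        (2C -> 2C/r -> heads*k²).
    heads: number of attention heads C_h; must divide the channel count.
    """

    kernel: int = 3
    reduction: int = 4
    heads: int = 1

    def __post_init__(self):
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError(f"context kernel must be odd and >= 1, got {self.kernel}")
        if self.reduction < 1:
            raise ValueError("reduction must be >= 1")
        if self.heads < 1:
            raise ValueError("heads must be >= 1")

    def validate_channels(self, channels: int) -> None:
        if channels % self.heads:
            raise ValueError(f"channels C={channels} not divisible by heads C_h={self.heads}")
        if (2 * channels) % self.reduction:
            raise ValueError(
                f"2*C={2 * channels} not divisible by attention reduction r={self.reduction}"
            )


@dataclass(frozen=True)
class ShuffleConfig:
    groups: int = 4

    def __post_init__(self):
        if self.groups < 1:
            raise ValueError("groups must be >= 1")


@dataclass(frozen=True)
class BlockSpec:
    """Declarative description of one residual block."""

    kind: str  # basic_cot | plain_basic | ccs_bottleneck | plain_bottleneck | bottleneck_shuffle_only
    in_channels: int
    mid_channels: int
    stride: int = 1
    groups: int = 1
    cot: CoTConfig | None = field(default=None)

    KINDS = (
        "basic_cot",
        "plain_basic",
        "ccs_bottleneck",
        "plain_bottleneck",
        "bottleneck_shuffle_only",
    )

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")
        if self.kind in ("ccs_bottleneck", "bottleneck_shuffle_only"):
            for c in (self.in_channels, self.mid_channels,
                      BOTTLENECK_EXPANSION * self.mid_channels):
                if c % self.groups:
                    raise ValueError(
                        f"channel count {c} not divisible by groups g={self.groups}"
                    )

    @property
    def out_channels(self) -> int:
        if self.kind in ("basic_cot", "plain_basic"):
            return self.mid_channels
        return BOTTLENECK_EXPANSION * self.mid_channels


# ---------------------------------------------------------------------------
# channel shuffle
# ---------------------------------------------------------------------------

def shuffle_permutation(channels: int, groups: int) -> np.ndarray:
    """Channel permutation realised by a shuffle with ``groups`` groups."""
    if channels % groups:
        raise ValueError(f"channel count C={channels} not divisible by groups g={groups}")
    return np.arange(channels).reshape(groups, channels // groups).T.reshape(-1)


def channel_shuffle(x, cfg: ShuffleConfig | int):
    """Interleave channel groups of a (N, C, H, W) feature map.

    Channels viewed as a (g, C/g) grid are transposed to (C/g, g) and
    flattened, so consecutive output channels come from distinct groups.
    Accepts a plain ndarray or an autodiff :class:`Tensor` (the permutation
    is differentiable).  Values are only permuted, never changed.
    """
    g = cfg.groups if isinstance(cfg, ShuffleConfig) else int(cfg)
    arr = x.data if isinstance(x, Tensor) else np.asarray(x)
    n, c, h, w = arr.shape
    if c % g:
        raise ValueError(f"channel count C={c} not divisible by groups g={g}")
    if isinstance(x, Tensor):
        return (
            x.reshape((n, g, c // g, h, w))
            .transpose((0, 2, 1, 3, 4))
            .reshape((n, c, h, w))
        )
    return arr.reshape(n, g, c // g, h, w).transpose(0, 2, 1, 3, 4).reshape(n, c, h, w)


# ---------------------------------------------------------------------------
# CoT block
# ---------------------------------------------------------------------------

class CoT(Module):
    """Contextual-transformer replacement for a 3×3 convolution.

    Output shape equals input shape; channel count is unchanged.
    """

    def __init__(self, channels: int, cfg: CoTConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = cfg or CoTConfig()
        cfg.validate_channels(channels)
        self.channels = channels
        self.cfg = cfg
        rng = rng or np.random.default_rng()
        k = cfg.kernel
        # static context: k×k convolution with same padding
        self.key_embed = Sequential(
            Conv2d(channels, channels, k, padding=k // 2, bias=False, rng=rng),
            BatchNorm2d(channels),
            ReLU(),
        )
        # value embedding W_v: pointwise
        self.value_embed = Sequential(
            Conv2d(channels, channels, 1, bias=False, rng=rng),
            BatchNorm2d(channels),
        )
        hidden = (2 * channels) // cfg.reduction
        # attention embedding W_theta, W_delta on [K1, Q]
        self.attention = Sequential(
            Conv2d(2 * channels, hidden, 1, bias=False, rng=rng),
            BatchNorm2d(hidden),
            ReLU(),
            Conv2d(hidden, cfg.heads * k * k, 1, bias=True, rng=rng),
        )

    def _check(self, x: Tensor) -> None:
        if x.shape[1] != self.channels:
            raise ValueError(
                f"CoT configured for C={self.channels} channels, input has C={x.shape[1]}"
            )

    def attention_weights(self, x: Tensor) -> Tensor:
        """Normalised aggregation weights, shape (N, heads, k², H, W)."""
        self._check(x)
        k, heads = self.cfg.kernel, self.cfg.heads
        n, _, h, w = x.shape
        k1 = self.key_embed(x)
        logits = self.attention(concat([k1, x], axis=1))
        return softmax(logits.reshape((n, heads, k * k, h, w)), axis=2)

    def forward(self, x: Tensor) -> Tensor:
        self._check(x)
        k, heads = self.cfg.kernel, self.cfg.heads
        n, c, h, w = x.shape
        k1 = self.key_embed(x)                     # static context K^1
        v = self.value_embed(x)                    # values V = X W_v
        logits = self.attention(concat([k1, x], axis=1))
        attn = softmax(logits.reshape((n, heads, k * k, h, w)), axis=2)
        # gather each position's k×k neighborhood of V and aggregate
        vn = unfold_nbhd(v, k, stride=1, padding=k // 2)      # (N, C, k², H, W)
        vn = vn.reshape((n, heads, c // heads, k * k, h, w))
        k2 = (attn.reshape((n, heads, 1, k * k, h, w)) * vn).sum(axis=3)
        k2 = k2.reshape((n, c, h, w))              # dynamic context K^2
        return k1 + k2


# ---------------------------------------------------------------------------
# residual blocks
# ---------------------------------------------------------------------------

def _projection(in_ch: int, out_ch: int, stride: int, rng) -> Module:
    return Sequential(
        Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng),
        BatchNorm2d(out_ch),
    )


class _ResidualBlock(Module):
    """Common skip-connection plumbing: out = ReLU(branch(x) + shortcut(x))."""

    def __init__(self, spec: BlockSpec, rng):
        super().__init__()
        self.spec = spec
        if spec.stride != 1 or spec.in_channels != spec.out_channels:
            self.shortcut = _projection(spec.in_channels, spec.out_channels, spec.stride, rng)
        else:
            self.shortcut = Identity()

    def branch(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def forward(self, x: Tensor) -> Tensor:
        return (self.branch(x) + self.shortcut(x)).relu()


class PlainBasicBlock(_ResidualBlock):
    """Standard ResNet-18 basic block: two 3×3 convolutions."""

    def __init__(self, spec: BlockSpec, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        super().__init__(spec, rng)
        mid = spec.mid_channels
        self.conv1 = Conv2d(spec.in_channels, mid, 3, stride=spec.stride, padding=1, rng=rng)
        self.bn1 = BatchNorm2d(mid)
        self.conv2 = Conv2d(mid, mid, 3, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(mid)

    def branch(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(y))


class BasicCoTBlock(_ResidualBlock):
    """Basic block with the second 3×3 convolution replaced by a CoT block.

    The first 3×3 convolution carries the stride (and any channel change);
    the CoT operates at the block's output width.
    """

    def __init__(self, spec: BlockSpec, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        super().__init__(spec, rng)
        mid = spec.mid_channels
        self.conv1 = Conv2d(spec.in_channels, mid, 3, stride=spec.stride, padding=1, rng=rng)
        self.bn1 = BatchNorm2d(mid)
        self.cot = CoT(mid, spec.cot or CoTConfig(), rng=rng)
        self.bn2 = BatchNorm2d(mid)

    def branch(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.cot(y))


class PlainBottleneck(_ResidualBlock):
    """Standard ResNet-50 bottleneck: 1×1 → 3×3 (stride) → 1×1 to 4×mid."""

    def __init__(self, spec: BlockSpec, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        super().__init__(spec, rng)
        mid = spec.mid_channels
        self.conv1 = Conv2d(spec.in_channels, mid, 1, rng=rng)
        self.bn1 = BatchNorm2d(mid)
        self.conv2 = Conv2d(mid, mid, 3, stride=spec.stride, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(mid)
        self.conv3 = Conv2d(mid, spec.out_channels, 1, rng=rng)
        self.bn3 = BatchNorm2d(spec.out_channels)

    def branch(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y)).relu()
        return self.bn3(self.conv3(y))


class _GroupedBottleneck(_ResidualBlock):
    """Shared structure of the shuffle-augmented bottlenecks.

    grouped 1×1 → shuffle → core (3×3 conv or CoT) → grouped 1×1 to 4×mid,
    plus skip.  The CoT core cannot stride, so downsampling blocks place a
    2×2 average pool (stride 2) before the core; the shortcut projects with
    a stride-2 1×1 convolution.
    """

    def __init__(self, spec: BlockSpec, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        super().__init__(spec, rng)
        mid, g = spec.mid_channels, spec.groups
        self.gconv1 = Conv2d(spec.in_channels, mid, 1, groups=g, rng=rng)
        self.bn1 = BatchNorm2d(mid)
        self.pool, self.core = self._make_core(spec, rng)
        self.bn2 = BatchNorm2d(mid)
        self.gconv2 = Conv2d(mid, spec.out_channels, 1, groups=g, rng=rng)
        self.bn3 = BatchNorm2d(spec.out_channels)

    def _make_core(self, spec: BlockSpec, rng):  # pragma: no cover - abstract
        raise NotImplementedError

    def branch(self, x: Tensor) -> Tensor:
        y = self.bn1(self.gconv1(x)).relu()
        y = channel_shuffle(y, self.spec.groups)
        y = self.pool(y)
        y = self.bn2(self.core(y)).relu()
        return self.bn3(self.gconv2(y))


class CCSBottleneck(_GroupedBottleneck):
    """CoT-with-channel-shuffle bottleneck (grouped 1×1 / shuffle / CoT).

    The CoT core cannot stride, so downsampling variants pool first.
    """

    def _make_core(self, spec: BlockSpec, rng):
        pool = AvgPool2d(2, 2) if spec.stride == 2 else Identity()
        return pool, CoT(spec.mid_channels, spec.cot or CoTConfig(), rng=rng)


class ShuffleBottleneck(_GroupedBottleneck):
    """Ablation bottleneck: grouped 1×1 + shuffle but a plain 3×3 core.

    With g=1 this collapses exactly to the plain bottleneck's parameterisation
    (the shuffle is the identity and grouping is degenerate).
    """

    def _make_core(self, spec: BlockSpec, rng):
        # a convolutional core strides itself, like the plain bottleneck
        conv = Conv2d(spec.mid_channels, spec.mid_channels, 3,
                      stride=spec.stride, padding=1, rng=rng)
        return Identity(), conv


_BLOCK_CLASSES = {
    "basic_cot": BasicCoTBlock,
    "plain_basic": PlainBasicBlock,
    "ccs_bottleneck": CCSBottleneck,
    "plain_bottleneck": PlainBottleneck,
    "bottleneck_shuffle_only": ShuffleBottleneck,
}


def build_block(spec: BlockSpec, rng: np.random.Generator | None = None) -> Module:
    """Instantiate the residual block described by ``spec``."""
    return _BLOCK_CLASSES[spec.kind](spec, rng=rng)
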