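"""Building blocks of the hierarchical-dilation vessel segmentation network.

Four composable feature-map transforms:

* :class:`ConvUnit` — the basic encoder/decoder unit, two stages of
  3x3 conv -> DropBlock -> BatchNorm -> ReLU (spatial dims preserved).
* :class:`HDCBlock` — hierarchical dilation convolution: the input is split
  into two channel halves, one convolved at dilation 1 and the other at
  dilation 2, the results concatenated, refined by spatial attention, and
  added back to the input through a residual connection. Channel count and
  resolution are unchanged, so the block drops into any U-shaped network.
* :class:`SpatialAttention` — channel-wise max and mean maps, concatenated,
  mixed by a single 7x7 conv and squashed to a per-pixel gate in (0, 1).
* :class:`RDECA` — residual dual efficient channel attention: global max and
  average descriptors are concatenated (2C), reduced back to C by a 1x1 conv,
  passed through a shared 1-D cross-channel conv, and turned into per-channel
  gates; a residual keeps the identity path.

DropBlock is the structured regularizer: instead of dropping isolated
activations it zeroes contiguous ``block_size`` x ``block_size`` patches,
which is far more effective on spatially correlated feature maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .layers import BatchNorm2d, Conv1dChannels, Conv2d, Module

__all__ = [
    "BlockConfig",
    "ConvUnit",
    "DropBlock2d",
    "HDCBlock",
    "RDECA",
    "SpatialAttention",
    "conv_unit",
    "dropblock",
    "hdc_block",
    "rdeca",
    "sam",
]


@dataclass
class BlockConfig:
    """Hyperparameters shared by all blocks.

    DropBlock block size 7 and drop rate 0.15 are the published training
    settings; the spatial-attention kernel is 7 and the cross-channel 1-D
    kernel is 3.
    """

    dropblock_block_size: int = 7
    dropblock_drop_rate: float = 0.15
    hdc_dilations: tuple[int, int] = (1, 2)
    sam_kernel: int = 7
    rdeca_1d_kernel: int = 3
    use_residual: bool = True

    def __post_init__(self):
        if self.dropblock_block_size < 1 or self.dropblock_block_size % 2 == 0:
            raise ValueError("dropblock_block_size must be odd and >= 1")
        if not 0.0 <= self.dropblock_drop_rate <= 1.0:
            raise ValueError("dropblock_drop_rate must lie in [0, 1]")
        if self.sam_kernel % 2 == 0:
            raise ValueError("sam_kernel must be odd")
        if self.rdeca_1d_kernel % 2 == 0:
            raise ValueError("rdeca_1d_kernel must be odd")


# ---------------------------------------------------------------------------
# DropBlock
# ---------------------------------------------------------------------------

def _dropblock_mask(shape, block_size: int, drop_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Binary keep-mask with contiguous zero blocks, one mask per channel."""
    b, c, h, w = shape
    if block_size > min(h, w):
        raise ValueError(
            f"block_size {block_size} exceeds feature map {h}x{w}"
        )
    valid_h = h - block_size + 1
    valid_w = w - block_size + 1
    gamma = drop_rate * h * w / (block_size**2 * valid_h * valid_w)
    seeds = rng.random((b, c, valid_h, valid_w)) < gamma
    keep = np.ones(shape, dtype=bool)
    # expand every seed to a block_size x block_size zero patch
    flat_seeds = seeds.reshape(b * c, valid_h, valid_w)
    keep_flat = keep.reshape(b * c, h, w)
    for bc, y, x in zip(*np.nonzero(flat_seeds)):
        keep_flat[bc, y : y + block_size, x : x + block_size] = False
    return keep


def dropblock(
    x: np.ndarray,
    block_size: int,
    drop_rate: float,
    training: bool,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Functional DropBlock on a raw (B, C, H, W) array.

    Training mode zeroes random contiguous patches and rescales survivors by
    total/kept so the expected activation is preserved; eval mode (or a zero
    rate) is the exact identity.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 4:
        raise ValueError(f"expected 4-D (B,C,H,W) input, got {x.ndim}-D")
    if not training or drop_rate == 0.0:
        if block_size > min(x.shape[2], x.shape[3]):
            raise ValueError(f"block_size {block_size} exceeds feature map")
        return x
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    keep = _dropblock_mask(x.shape, block_size, drop_rate, rng)
    kept = keep.sum()
    if kept == 0:
        return np.zeros_like(x)
    return x * keep * (keep.size / kept)


class DropBlock2d(Module):
    def __init__(self, block_size: int, drop_rate: float):
        self.block_size = block_size
        self.drop_rate = drop_rate

    def forward(self, x: Tensor, training: bool = False, rng: np.random.Generator | None = None):
        if not training or self.drop_rate == 0.0:
            return x
        rng = rng or np.random.default_rng(0)
        # deep levels of a U shape can be smaller than the nominal block
        block = min(self.block_size, x.shape[2], x.shape[3])
        keep = _dropblock_mask(x.shape, block, self.drop_rate, rng)
        kept = keep.sum()
        scale = keep.size / kept if kept else 0.0
        return ag.mul(x, ag.as_tensor(keep * scale))


# ---------------------------------------------------------------------------
# basic convolution unit
# ---------------------------------------------------------------------------

class ConvUnit(Module):
    """Two stages of 3x3 conv (padding 1) -> DropBlock -> BN -> ReLU."""

    def __init__(self, cin: int, cout: int, cfg: BlockConfig, use_dropblock: bool = True, rng=None):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(cin, cout, 3, padding=1, rng=rng)
        self.conv2 = Conv2d(cout, cout, 3, padding=1, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.bn2 = BatchNorm2d(cout)
        self.drop = (
            DropBlock2d(cfg.dropblock_block_size, cfg.dropblock_drop_rate) if use_dropblock else None
        )

    def forward(self, x: Tensor, training: bool = False, rng=None):
        if x.ndim != 4:
            raise ValueError(f"expected 4-D (B,C,H,W) input, got {x.ndim}-D")
        for conv, bn in ((self.conv1, self.bn1), (self.conv2, self.bn2)):
            x = conv.forward(x, training)
            if self.drop is not None:
                x = self.drop.forward(x, training, rng)
            x = bn.forward(x, training)
            x = ag.relu(x)
        return x


# ---------------------------------------------------------------------------
# spatial attention
# ---------------------------------------------------------------------------

class SpatialAttention(Module):
    """Per-pixel gate from channel-pooled maps: sigma(conv_kxk(cat[max, mean]))."""

    def __init__(self, kernel: int = 7, rng=None):
        if kernel % 2 == 0:
            raise ValueError(f"spatial attention kernel must be odd, got {kernel}")
        self.conv = Conv2d(2, 1, kernel, padding=kernel // 2, rng=rng)

    def forward(self, x: Tensor, training: bool = False, rng=None):
        pooled = ag.concat([ag.channel_max(x), ag.channel_mean(x)], axis=1)
        return ag.sigmoid(self.conv.forward(pooled, training))


# ---------------------------------------------------------------------------
# hierarchical dilation convolution block
# ---------------------------------------------------------------------------

class HDCBlock(Module):
    """Split -> parallel dilated convs -> concat -> spatial attention -> residual.

    The two channel halves see receptive fields of different sizes (dilation
    1 and 2), so thick and fragile thin vessels are detected by different
    filter groups; the attention map re-weights the fused response before the
    residual restores the identity path.
    """

    def __init__(self, channels: int, cfg: BlockConfig, rng=None):
        if channels % 2:
            raise ValueError(f"HDC input channels must be even, got {channels}")
        rng = rng or np.random.default_rng(0)
        half = channels // 2
        d1, d2 = cfg.hdc_dilations
        self.conv_d1 = Conv2d(half, half, 3, padding=d1, dilation=d1, rng=rng)
        self.conv_d2 = Conv2d(half, half, 3, padding=d2, dilation=d2, rng=rng)
        self.sam = SpatialAttention(cfg.sam_kernel, rng=rng)
        self.half = half

    def forward(self, x: Tensor, training: bool = False, rng=None):
        if x.ndim != 4:
            raise ValueError(f"expected 4-D (B,C,H,W) input, got {x.ndim}-D")
        if x.shape[1] != 2 * self.half:
            raise ValueError(f"expected {2 * self.half} channels, got {x.shape[1]}")
        x1 = ag.narrow(x, 1, 0, self.half)
        x2 = ag.narrow(x, 1, self.half, self.half)
        y3 = ag.concat([self.conv_d1.forward(x1), self.conv_d2.forward(x2)], axis=1)
        gate = self.sam.forward(y3, training)
        return ag.add(x, ag.mul(gate, y3))


# ---------------------------------------------------------------------------
# residual dual efficient channel attention
# ---------------------------------------------------------------------------

class RDECA(Module):
    """Channel gates from dual global pooling, with an additive residual.

    Global max and average descriptors are concatenated along channels (2C),
    reduced to C by a 1x1 conv + ReLU, mixed across neighbouring channels by
    a shared 1-D conv, and squashed to gates w in (0,1)^C. Output is
    ``x + x*w`` (or ``x*w`` with the residual ablated).
    """

    def __init__(self, channels: int, cfg: BlockConfig, rng=None):
        if channels < cfg.rdeca_1d_kernel:
            raise ValueError(
                f"need at least {cfg.rdeca_1d_kernel} channels, got {channels}"
            )
        rng = rng or np.random.default_rng(0)
        self.reduce = Conv2d(2 * channels, channels, 1, rng=rng)
        self.conv1d = Conv1dChannels(cfg.rdeca_1d_kernel, rng=rng)
        self.use_residual = cfg.use_residual

    def forward(self, x: Tensor, training: bool = False, rng=None):
        if x.ndim != 4:
            raise ValueError(f"expected 4-D (B,C,H,W) input, got {x.ndim}-D")
        desc = ag.concat([ag.spatial_max(x), ag.spatial_mean(x)], axis=1)
        desc = ag.relu(self.reduce.forward(desc, training))
        gate = ag.sigmoid(self.conv1d.forward(desc, training))
        gated = ag.mul(x, gate)
        return ag.add(x, gated) if self.use_residual else gated


# ---------------------------------------------------------------------------
# functional wrappers (ndarray in, ndarray out; deterministic default weights)
# ---------------------------------------------------------------------------

def _as_batch(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 4:
        raise ValueError(f"expected 4-D (B,C,H,W) input, got {x.ndim}-D")
    return x


def conv_unit(x, out_channels: int, cfg: BlockConfig | None = None, training: bool = False, seed: int = 0):
    cfg = cfg or BlockConfig()
    x = _as_batch(x)
    unit = ConvUnit(x.shape[1], out_channels, cfg, rng=np.random.default_rng(seed))
    return unit.forward(ag.as_tensor(x), training, np.random.default_rng(seed)).data


def sam(y3, kernel: int = 7, seed: int = 0):
    y3 = _as_batch(y3)
    module = SpatialAttention(kernel, rng=np.random.default_rng(seed))
    return module.forward(ag.as_tensor(y3)).data


def hdc_block(f, cfg: BlockConfig | None = None, training: bool = False, seed: int = 0):
    cfg = cfg or BlockConfig()
    f = _as_batch(f)
    block = HDCBlock(f.shape[1], cfg, rng=np.random.default_rng(seed))
    return block.forward(ag.as_tensor(f), training).data


def rdeca(x, cfg: BlockConfig | None = None, seed: int = 0):
    cfg = cfg or BlockConfig()
    x = _as_batch(x)
    module = RDECA(x.shape[1], cfg, rng=np.random.default_rng(seed))
    return module.forward(ag.as_tensor(x)).data
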