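"""U-shaped segmentation networks: the HDC-Net assembly and its ablations.

The variant lattice mirrors the ablation study: a plain U-Net baseline,
the structured-dropout backbone (SD-UNet), the backbone plus channel
attention on the skips (with and without the residual), the backbone plus
hierarchical dilation blocks, and the full model.

The default configuration is depth 3 (three 2x2 poolings) with 32 base
channels doubling per level, recovered by an exhaustive calibration search
as the unique clean configuration whose plain-U-Net trainable-parameter
count equals the published 2,143,905 (double 3x3 convs with bias and batch
norm, kernel-3 stride-2 transposed convolutions halving channels, batch
norm on the up path, 1x1 sigmoid head).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .arch_blocks import BlockConfig, ConvUnit, HDCBlock, RDECA
from .layers import BatchNorm2d, Conv2d, ConvTranspose2d, Module

__all__ = ["ModelConfig", "SegmentationModel", "VARIANTS", "build_model", "count_parameters", "predict"]


#: variant name -> (use_dropblock, use_hdc, use_rdeca, rdeca_residual)
VARIANTS: dict[str, tuple[bool, bool, bool, bool]] = {
    "unet": (False, False, False, True),
    "sd_unet": (True, False, False, True),
    "sd_unet_rdeca": (True, False, True, True),
    "sd_unet_rdeca_no_rc": (True, False, True, False),
    "sd_unet_hdc": (True, True, False, True),
    "hdcnet": (True, True, True, True),
    "hdcnet_no_rc": (True, True, True, False),
}


@dataclass
class ModelConfig:
    """Architecture variant plus the width/depth of the U shape."""

    variant: str = "hdcnet"
    depth: int = 3
    base_channels: int = 32
    block: BlockConfig = field(default_factory=BlockConfig)
    in_channels: int = 3
    out_channels: int = 1

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {sorted(VARIANTS)}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels % 2:
            raise ValueError("base_channels must be even (HDC splits channels in half)")
        if not VARIANTS[self.variant][3] and VARIANTS[self.variant][2]:
            # ablated residual is carried on the block config
            self.block = replace(self.block, use_residual=False)


class SegmentationModel(Module):
    """Encoder–decoder with optional HDC blocks and RDECA skip attention."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        use_db, use_hdc, use_rdeca, _ = VARIANTS[cfg.variant]
        self.cfg = cfg
        widths = [cfg.base_channels * 2**i for i in range(cfg.depth)]
        bottleneck = cfg.base_channels * 2**cfg.depth

        self.encoders: list[ConvUnit] = []
        self.enc_hdc: list[HDCBlock | None] = []
        cin = cfg.in_channels
        for w in widths:
            self.encoders.append(ConvUnit(cin, w, cfg.block, use_db, rng=rng))
            self.enc_hdc.append(HDCBlock(w, cfg.block, rng=rng) if use_hdc else None)
            cin = w
        self.bottleneck = ConvUnit(widths[-1], bottleneck, cfg.block, use_db, rng=rng)
        self.bott_hdc = HDCBlock(bottleneck, cfg.block, rng=rng) if use_hdc else None

        self.ups: list[ConvTranspose2d] = []
        self.up_bns: list[BatchNorm2d] = []
        self.skips: list[RDECA | None] = []
        self.decoders: list[ConvUnit] = []
        self.dec_hdc: list[HDCBlock | None] = []
        cin = bottleneck
        for w in reversed(widths):
            self.ups.append(ConvTranspose2d(cin, cin // 2, rng=rng))
            self.up_bns.append(BatchNorm2d(cin // 2))
            self.skips.append(RDECA(w, cfg.block, rng=rng) if use_rdeca else None)
            self.decoders.append(ConvUnit(w + cin // 2, w, cfg.block, use_db, rng=rng))
            self.dec_hdc.append(HDCBlock(w, cfg.block, rng=rng) if use_hdc else None)
            cin = w
        self.head = Conv2d(widths[0], cfg.out_channels, 1, rng=rng)

    def forward(self, x: Tensor, training: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        if x.ndim != 4:
            raise ValueError(f"expected 4-D (B,C,H,W) input, got {x.ndim}-D")
        h, w = x.shape[2], x.shape[3]
        div = 2**self.cfg.depth
        if h % div or w % div:
            raise ValueError(
                f"spatial dims {h}x{w} not divisible by 2^depth={div}; "
                f"pad to {-(-h // div) * div}x{-(-w // div) * div} first"
            )
        skips = []
        for enc, hdc in zip(self.encoders, self.enc_hdc):
            x = enc.forward(x, training, rng)
            if hdc is not None:
                x = hdc.forward(x, training, rng)
            skips.append(x)
            x = ag.maxpool2x2(x)
        x = self.bottleneck.forward(x, training, rng)
        if self.bott_hdc is not None:
            x = self.bott_hdc.forward(x, training, rng)
        for up, bn, gate, dec, hdc, skip in zip(
            self.ups, self.up_bns, self.skips, self.decoders, self.dec_hdc, reversed(skips)
        ):
            x = bn.forward(up.forward(x, training), training)
            if gate is not None:
                skip = gate.forward(skip, training)
            x = ag.concat([skip, x], axis=1)
            x = dec.forward(x, training, rng)
            if hdc is not None:
                x = hdc.forward(x, training, rng)
        return ag.sigmoid(self.head.forward(x, training))


def build_model(cfg: ModelConfig, seed: int = 0) -> SegmentationModel:
    """Assemble a segmentation network for the given variant."""
    return SegmentationModel(cfg, seed=seed)


def count_parameters(model: SegmentationModel) -> int:
    """Total trainable scalars (conv/transposed-conv kernels, biases, BN scale/shift)."""
    return model.count_parameters()


def predict(model: SegmentationModel, image: np.ndarray, cfg: ModelConfig | None = None) -> np.ndarray:
    """Per-pixel vessel probability map for one H x W x 3 image in [0, 1].

    Deterministic (eval mode); spatial dims must be divisible by 2^depth —
    pad with the data pipeline first.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {image.shape}")
    x = image.transpose(2, 0, 1)[None]
    out = model.forward(ag.as_tensor(x), training=False)
    return out.data[0, 0]
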