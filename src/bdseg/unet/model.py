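"""3D U-Net for breast segmentation.

Two input channels (fat-only and water-only).  Each encoder level applies
two padded 3x3x3 convolutions, each followed by ReLU and batch
normalization, then 2x2x2 max pooling; each decoder level applies a
2x2x2 transposed convolution, concatenates the same-size encoder feature
map, and applies two conv+ReLU+BN blocks.  The head is a 1x1x1
convolution followed by a probability-producing squashing; channel
widths double per level.

Down/upsampling uses stride 2 (a stride of 1 would abolish the
resolution pyramid and the same-size skip pattern).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .layers import (
    Adam,
    BatchNorm3d,
    Concat,
    Conv3d,
    ConvTranspose3d,
    Layer,
    MaxPool3d,
    ReLU,
    Sigmoid,
)

__all__ = ["UNetConfig", "UNet3D", "build_unet"]


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 4
    base_channels: int = 32
    in_channels: int = 2
    batch_size: int = 3
    lr_initial: float = 1e-3
    lr_factor: float = 0.33
    lr_patience_epochs: int = 50
    lr_floor: float = 1e-5
    early_stop_epochs: int = 200
    loss_name: str = "dice"
    #: "sigmoid" squashes the head logits directly; "relu_sigmoid" applies
    #: ReLU first (as printed), which floors probabilities at 0.5
    final_activation: str = "sigmoid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if not self.lr_floor < self.lr_initial:
            raise ValueError("lr_floor must be < lr_initial")
        if self.loss_name not in ("dice", "bce", "dice+bce"):
            raise ValueError("loss_name must be dice, bce, or dice+bce")
        if self.final_activation not in ("sigmoid", "relu_sigmoid"):
            raise ValueError("final_activation must be sigmoid or relu_sigmoid")


class _ConvBlock:
    """[conv3 + ReLU + BN] x 2."""

    def __init__(self, c_in: int, c_out: int, rng):
        self.seq: List[Layer] = [
            Conv3d(c_in, c_out, 3, rng), ReLU(), BatchNorm3d(c_out),
            Conv3d(c_out, c_out, 3, rng), ReLU(), BatchNorm3d(c_out),
        ]

    def forward(self, x, train):
        for l in self.seq:
            x = l.forward(x, train)
        return x

    def backward(self, dout):
        for l in reversed(self.seq):
            dout = l.backward(dout)
        return dout


class UNet3D:
    """Encoder-decoder with skip concatenation; probability output."""

    def __init__(self, cfg: UNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = [cfg.base_channels * 2 ** i for i in range(cfg.depth)]
        self.enc_blocks = []
        c_prev = cfg.in_channels
        for c in ch:
            self.enc_blocks.append(_ConvBlock(c_prev, c, rng))
            c_prev = c
        self.pools = [MaxPool3d() for _ in range(cfg.depth - 1)]
        self.ups: List[ConvTranspose3d] = []
        self.dec_blocks: List[_ConvBlock] = []
        self.concats: List[Concat] = []
        for i in range(cfg.depth - 2, -1, -1):
            self.ups.append(ConvTranspose3d(ch[i + 1], ch[i], rng))
            self.concats.append(Concat())
            self.dec_blocks.append(_ConvBlock(2 * ch[i], ch[i], rng))
        self.head = Conv3d(ch[0], 1, 1, rng)
        self.head_relu = ReLU()
        self.head_sigmoid = Sigmoid()

    # -- plumbing ----------------------------------------------------------
    def layers(self) -> List[Layer]:
        out: List[Layer] = []
        for b in self.enc_blocks:
            out.extend(b.seq)
        for u, b in zip(self.ups, self.dec_blocks):
            out.append(u)
            out.extend(b.seq)
        out.append(self.head)
        return out

    def num_parameters(self) -> int:
        return sum(int(p.size) for l in self.layers() for p in l.params.values())

    def check_shape(self, spatial: Tuple[int, int, int]) -> None:
        f = 2 ** (self.cfg.depth - 1)
        if any(s % f for s in spatial):
            raise ValueError(
                f"input spatial shape {spatial} must be divisible by {f} "
                f"(2^(depth-1)); pad the volume first")

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self.check_shape(x.shape[2:])
        skips = []
        for i, block in enumerate(self.enc_blocks):
            x = block.forward(x, train)
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x, train)
        for up, cat, block, skip in zip(self.ups, self.concats,
                                        self.dec_blocks, reversed(skips)):
            x = up.forward(x, train)
            x = cat.forward_pair(skip, x)
            x = block.forward(x, train)
        x = self.head.forward(x, train)
        if self.cfg.final_activation == "relu_sigmoid":
            x = self.head_relu.forward(x, train)
        return self.head_sigmoid.forward(x, train)

    def backward(self, dprob: np.ndarray) -> None:
        d = self.head_sigmoid.backward(dprob)
        if self.cfg.final_activation == "relu_sigmoid":
            d = self.head_relu.backward(d)
        d = self.head.backward(d)
        # walking the decoder backwards visits skips shallow -> deep, so
        # dskips[i] ends up matching encoder level i
        dskips = []
        for up, cat, block in zip(reversed(self.ups), reversed(self.concats),
                                  reversed(self.dec_blocks)):
            d = block.backward(d)
            dskip, d = cat.backward(d)
            dskips.append(dskip)
            d = up.backward(d)
        for i in range(len(self.enc_blocks) - 1, -1, -1):
            if i < len(self.pools):
                d = self.pools[i].backward(d)
                d = d + dskips[i]
            d = self.enc_blocks[i].backward(d)

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.layers(), lr=lr)


def build_unet(cfg: UNetConfig) -> UNet3D:
    """Construct a seeded, untrained network from a validated config."""
    return UNet3D(cfg)
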