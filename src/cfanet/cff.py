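"""Context feature fusion for skip connections.

Each fusion block takes an ordered run of encoder features (shallowest
first), projects every input to the channel width of the shallowest one,
upsamples the deeper inputs to the shallowest resolution, concatenates, and
extracts multi-scale context with parallel 1x1 / 3x3 / 5x5 convolutions
before a final 1x1 projection back to the target width.

Channel unification uses 1x1 projections: with 3x3 unify convolutions the
assembled network would exceed its documented ~30M parameter total by ~3M,
while 1x1 channel projection hits it exactly and leaves the multi-scale
pipeline untouched.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import nn
from .nn import functional as F
from .nn.autograd import Tensor

__all__ = ["CffBlock", "make_cff_bank", "DEFAULT_ENCODER_CHANNELS"]

DEFAULT_ENCODER_CHANNELS = (64, 128, 256, 512)

#: kernel sizes of the parallel context branches
SCALE_KERNELS = (1, 3, 5)


def _unit(in_ch: int, out_ch: int, kernel: int, norm_act: bool,
          rng: np.random.Generator | None) -> nn.Module:
    # edge padding keeps constants exact fixed points of averaging kernels
    # and avoids zero-border artifacts in the fused context features
    if norm_act:
        return nn.ConvBNReLU(in_ch, out_ch, kernel, padding_mode="edge", rng=rng)
    return nn.Conv2d(in_ch, out_ch, kernel, padding=kernel // 2, bias=True,
                     padding_mode="edge", rng=rng)


class CffBlock(nn.Module):
    """Fuse 2-3 pyramid levels into the shallowest level's resolution/width.

    Parameters
    ----------
    in_channels:
        Channel widths of the fused inputs, shallowest first.  The output
        width equals ``in_channels[0]``.
    norm_act:
        When True (default) every convolution except the final projection is
        followed by batch norm + ReLU.  When False the block is purely
        linear (biased convolutions, no normalisation) — used by closed-form
        equivalence checks.
    """

    def __init__(self, in_channels: Sequence[int], norm_act: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        in_channels = tuple(in_channels)
        if not 1 <= len(in_channels) <= 3:
            raise ValueError(f"expected 1-3 fused inputs, got {len(in_channels)}")
        c_t = in_channels[0]
        self.in_channels = in_channels
        self.out_channels = c_t
        self.unify = nn.ModuleList(
            _unit(c, c_t, 1, norm_act, rng) for c in in_channels
        )
        concat_ch = c_t * len(in_channels)
        self.scales = nn.ModuleList(
            _unit(concat_ch, c_t, k, norm_act, rng) for k in SCALE_KERNELS
        )
        self.project = nn.Conv2d(len(SCALE_KERNELS) * c_t, c_t, 1, bias=True, rng=rng)

    def forward(self, features: Sequence[Tensor]) -> Tensor:
        if len(features) == 0:
            raise ValueError("CffBlock requires at least one input feature map")
        if len(features) != len(self.unify):
            raise ValueError(
                f"expected {len(self.unify)} inputs, got {len(features)}"
            )
        _, _, h0, w0 = features[0].shape
        for i in range(len(features) - 1):
            _, _, ha, wa = features[i].shape
            _, _, hb, wb = features[i + 1].shape
            if (hb * 2, wb * 2) != (ha, wa):
                raise ValueError(
                    f"fused input {i + 1} has spatial dims {(hb, wb)}, "
                    f"expected exactly half of {(ha, wa)}"
                )
        unified = []
        for feat, proj in zip(features, self.unify):
            u = proj(feat)
            unified.append(F.upsample_bilinear(u, (h0, w0)))
        fused = F.concat(unified, axis=1)  # C1: len(features) * C_t channels
        branches = [scale(fused) for scale in self.scales]
        return self.project(F.concat(branches, axis=1))


def make_cff_bank(
    encoder_channels: Sequence[int] = DEFAULT_ENCODER_CHANNELS,
    norm_act: bool = True,
    rng: np.random.Generator | None = None,
) -> nn.ModuleList:
    """Build the three fusion blocks used at the skip connections.

    With the default pyramid (64, 128, 256, 512) the blocks fuse
    (s1, s2, s3), (s2, s3, s4) and (s3, s4); output widths (64, 128, 256).
    """
    channels = tuple(encoder_channels)
    if len(channels) < 4:
        raise ValueError(
            f"need 4 encoder stages to place 3 fusion blocks, got {len(channels)}"
        )
    bank = nn.ModuleList()
    for level in range(3):
        fused = channels[level:level + 3]  # truncates to 2 at the deepest level
        if level < 2 and len(fused) < 3:
            raise ValueError(
                f"fusion level {level + 1} needs 2 deeper stages, "
                f"only {len(fused) - 1} available"
            )
        bank.append(CffBlock(fused, norm_act=norm_act, rng=rng))
    return bank
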