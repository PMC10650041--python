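"""Channel + spatial attention block applied at the encoder bottleneck.

Channel attention pools the input globally (max and average), pushes both
pooled vectors through a shared two-layer 1x1-convolution bottleneck, sums
the branch outputs, and squashes with a sigmoid; the resulting per-channel
weights rescale the input.  Spatial attention then compresses channels with
per-pixel max and mean, concatenates the two maps, and derives a per-pixel
weight through a 7x7 convolution + sigmoid.  The block output adds the
doubly-reweighted features back onto the input (residual).
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import functional as F
from .nn.autograd import Tensor

__all__ = ["EcsaBlock"]


class EcsaBlock(nn.Module):
    """Effective channel-spatial attention with residual output.

    Parameters
    ----------
    channels:
        Input channel count ``C``.
    reduction:
        Bottleneck reduction ratio ``r``; must divide ``C``.  The two 1x1
        convolutions are shared between the max-pool and avg-pool branches.
    """

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % reduction != 0:
            raise ValueError(
                f"reduction ratio {reduction} must divide channel count {channels}"
            )
        self.channels = channels
        self.reduction = reduction
        hidden = channels // reduction
        self.fc1 = nn.Conv2d(channels, hidden, 1, bias=True, rng=rng)
        self.fc2 = nn.Conv2d(hidden, channels, 1, bias=True, rng=rng)
        self.spatial = nn.Conv2d(2, 1, 7, padding=3, bias=True, rng=rng)

    def _bottleneck(self, pooled: Tensor) -> Tensor:
        return self.fc2(F.relu(self.fc1(pooled)))

    def channel_attention(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Return ``(weights, reweighted)``: weights are (N, C, 1, 1) in (0,1)."""
        mp = self._bottleneck(F.global_max_pool(x))
        ap = self._bottleneck(F.global_avg_pool(x))
        weights = F.sigmoid(mp + ap)
        return weights, weights * x

    def spatial_attention(self, a_channel: Tensor) -> tuple[Tensor, Tensor]:
        """Return ``(map, reweighted)``: map is (N, 1, H, W) in (0,1)."""
        desc = F.concat([F.channel_max(a_channel), F.channel_mean(a_channel)], axis=1)
        amap = F.sigmoid(self.spatial(desc))
        return amap, amap * a_channel

    def forward(self, x: Tensor) -> Tensor:
        _, a_channel = self.channel_attention(x)
        _, a_spatial = self.spatial_attention(a_channel)
        return x + a_spatial
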