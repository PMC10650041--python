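"""ResNet34-style feature extractor without the classification head.

The backbone exposes one feature map per stage so that skip connections and
the bottleneck attention block can tap the pyramid at strides 2..32.  Layer
naming follows the standard ResNet34 convention (``conv1``, ``bn1``,
``layer1.0.conv1`` ...) so that flat name->tensor checkpoints trained
elsewhere load directly; entries for the removed average-pool/fully-connected
head are skipped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import functional as F
from .nn.autograd import Tensor

logger = logging.getLogger(__name__)

__all__ = ["EncoderPyramid", "ResNetEncoder", "DimensionError"]

#: channel width of each pyramid stage, in stride order (2, 4, 8, 16, 32)
STAGE_CHANNELS = (64, 64, 128, 256, 512)
#: number of residual blocks per stage for the 34-layer configuration
STAGE_DEPTHS = (3, 4, 6, 3)


class DimensionError(ValueError):
    """Raised when a spatial dimension violates the stride contract."""


@dataclass
class EncoderPyramid:
    """Multi-resolution encoder features.

    ``s0`` is the post-stem map at stride 2; ``s1``..``s4`` follow at strides
    4, 8, 16 and 32 with channel widths (64, 64, 128, 256, 512).
    """

    s0: Tensor
    s1: Tensor
    s2: Tensor
    s3: Tensor
    s4: Tensor

    def stages(self) -> tuple[Tensor, ...]:
        return (self.s0, self.s1, self.s2, self.s3, self.s4)


class BasicBlock(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.downsample = nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng),
                nn.BatchNorm2d(out_ch),
            )
        else:
            self.downsample = None

    def forward(self, x: Tensor) -> Tensor:
        out = F.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        identity = self.downsample(x) if self.downsample is not None else x
        return F.relu(out + identity)


def _check_divisible(h: int, w: int) -> None:
    for axis, size in (("height", h), ("width", w)):
        if size < 32 or size % 32 != 0:
            raise DimensionError(
                f"input {axis} {size} must be a multiple of 32 and >= 32"
            )


class ResNetEncoder(nn.Module):
    """34-layer residual encoder; avgpool and fc are absent by construction."""

    def __init__(self, in_channels: int = 3, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        self.conv1 = nn.Conv2d(in_channels, 64, 7, stride=2, padding=3, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(64)
        widths = STAGE_CHANNELS[1:]
        in_ch = 64
        for i, (out_ch, depth) in enumerate(zip(widths, STAGE_DEPTHS), start=1):
            stride = 1 if i == 1 else 2  # stage 1 follows the stem max-pool
            blocks = [BasicBlock(in_ch, out_ch, stride=stride, rng=rng)]
            blocks += [BasicBlock(out_ch, out_ch, rng=rng) for _ in range(depth - 1)]
            setattr(self, f"layer{i}", nn.Sequential(*blocks))
            in_ch = out_ch

    def forward(self, image: Tensor) -> EncoderPyramid:
        return self.encode(image)

    def encode(self, image: Tensor) -> EncoderPyramid:
        """Run the backbone and return the full feature pyramid."""
        if not isinstance(image, Tensor):
            image = Tensor(image)
        if image.ndim != 4:
            raise DimensionError(f"expected NCHW input, got ndim={image.ndim}")
        _, _, h, w = image.shape
        _check_divisible(h, w)
        s0 = F.relu(self.bn1(self.conv1(image)))
        x = F.max_pool2d(s0, kernel=3, stride=2, padding=1)
        s1 = self.layer1(x)
        s2 = self.layer2(s1)
        s3 = self.layer3(s2)
        s4 = self.layer4(s3)
        return EncoderPyramid(s0, s1, s2, s3, s4)

    def load_pretrained_weights(self, weights_source) -> int:
        """Load a flat ResNet34 checkpoint (``.npz`` path or name->array dict).

        Entries belonging to the removed head (``fc.*``) or unknown to the
        backbone are skipped and their count logged/returned.  A shape
        mismatch on a retained layer raises with the offending layer name.
        """
        if isinstance(weights_source, (str, Path)):
            path = Path(weights_source)
            if not path.exists():
                raise FileNotFoundError(f"weights file not found: {path}")
            with np.load(path) as npz:
                state = {k: npz[k] for k in npz.files}
        else:
            state = dict(weights_source)
        # tolerate "num_batches_tracked" style bookkeeping entries
        state = {k: v for k, v in state.items() if np.asarray(v).ndim > 0 or "track" not in k}
        # strict on retained layers: a checkpoint of a different depth lacks
        # whole blocks and must fail loudly rather than load partially
        skipped = self.load_state_dict(state, strict=True)
        if skipped:
            logger.info(
                "skipped %d checkpoint entries not present in the headless backbone: %s",
                len(skipped), ", ".join(sorted(skipped)[:8]),
            )
        return len(skipped)
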