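"""Decoder blocks and the assembled segmentation network.

The network is a U-shape: the residual encoder produces a stride-2..32
pyramid; the bottleneck features pass through the attention block (optional);
the decoder runs five conv->upsample blocks, summing fusion-module outputs
(or raw skips when fusion is disabled) at strides 16, 8 and 4; a final 1x1
convolution produces per-pixel logits at input resolution.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .nn import functional as F
from .nn.autograd import Tensor, no_grad
from .cff import make_cff_bank
from .ecsa import EcsaBlock
from .encoder import DimensionError, ResNetEncoder, STAGE_CHANNELS

__all__ = [
    "NetworkConfig", "DecoderBlock", "CFANet",
    "count_parameters", "save_checkpoint", "load_checkpoint",
]

DEFAULT_DECODER_LADDER = (512, 256, 128, 64, 64, 32)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters; fully determines the parameter count."""

    num_classes: int = 1
    input_channels: int = 3
    use_cff: bool = True
    use_ecsa: bool = True
    ecsa_reduction: int = 16
    decoder_ladder: tuple[int, ...] = DEFAULT_DECODER_LADDER
    pretrained: bool = False
    seed: int = 0

    def __post_init__(self):
        if len(self.decoder_ladder) != 6:
            raise ValueError(
                "decoder ladder must list 6 widths (input + 5 upsample steps), "
                f"got {len(self.decoder_ladder)}"
            )
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["decoder_ladder"] = list(self.decoder_ladder)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if "decoder_ladder" in d:
            d["decoder_ladder"] = tuple(d["decoder_ladder"])
        return cls(**d)


class DecoderBlock(nn.Module):
    """3x3 conv (BN+ReLU) -> bilinear x2 upsample -> optional sum with skip."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.conv = nn.ConvBNReLU(in_ch, out_ch, 3, rng=rng)

    def forward(self, x: Tensor, skip: Tensor | None = None) -> Tensor:
        y = self.conv(x)
        _, _, h, w = y.shape
        y = F.upsample_bilinear(y, (2 * h, 2 * w))
        if skip is not None:
            if skip.shape != y.shape:
                raise DimensionError(
                    f"skip shape {tuple(skip.shape)} does not match "
                    f"upsampled decoder shape {tuple(y.shape)}"
                )
            y = y + skip
        return y


class CFANet(nn.Module):
    """U-shaped segmentation network with optional fusion/attention modules."""

    def __init__(self, config: NetworkConfig | None = None):
        super().__init__()
        self.config = config = config or NetworkConfig()
        rng = np.random.default_rng(config.seed)
        self.encoder = ResNetEncoder(config.input_channels, rng=rng)
        if config.use_ecsa:
            self.ecsa = EcsaBlock(STAGE_CHANNELS[-1], config.ecsa_reduction, rng=rng)
        else:
            self.ecsa = None
        if config.use_cff:
            self.cff = make_cff_bank(STAGE_CHANNELS[1:], rng=rng)
        else:
            self.cff = None
        ladder = config.decoder_ladder
        self.blocks = nn.ModuleList(
            DecoderBlock(ladder[i], ladder[i + 1], rng=rng) for i in range(5)
        )
        self.head = nn.Conv2d(ladder[5], config.num_classes, 1, bias=True, rng=rng)

    def forward(self, image) -> Tensor:
        if not isinstance(image, Tensor):
            image = Tensor(image)
        pyr = self.encoder.encode(image)
        bottom = self.ecsa(pyr.s4) if self.ecsa is not None else pyr.s4
        if self.cff is not None:
            skips = [
                self.cff[0]([pyr.s1, pyr.s2, pyr.s3]),
                self.cff[1]([pyr.s2, pyr.s3, pyr.s4]),
                self.cff[2]([pyr.s3, pyr.s4]),
            ]
        else:
            skips = [pyr.s1, pyr.s2, pyr.s3]
        y = self.blocks[0](bottom, skips[2])   # stride 32 -> 16
        y = self.blocks[1](y, skips[1])        # -> 8
        y = self.blocks[2](y, skips[0])        # -> 4
        y = self.blocks[3](y)                  # -> 2
        y = self.blocks[4](y)                  # -> 1
        return self.head(y)

    def predict_proba(self, image) -> np.ndarray:
        """Sigmoid probabilities in inference mode (no tape, batch-stat-free)."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                logits = self.forward(image)
        finally:
            self.train(was_training)
        from scipy.special import expit

        return expit(logits.data)


def count_parameters(config: NetworkConfig | None = None, as_millions: bool = False):
    """Exact trainable-parameter total for a configuration.

    With ``as_millions=True`` the count is returned in millions rounded to
    the nearest integer (the convention used in efficiency tables).
    """
    net = CFANet(config or NetworkConfig())
    total = net.num_parameters()
    if as_millions:
        return int(round(total / 1e6))
    return total


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: CFANet, extra: dict | None = None) -> None:
    """Serialize weights + config (and optional metadata) to an ``.npz``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"config": model.config.to_dict()}
    if extra:
        meta.update(extra)
    arrays = {f"state/{k}": v for k, v in model.state_dict().items()}
    arrays["__meta__"] = np.frombuffer(
        yaml.safe_dump(meta).encode("utf-8"), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[CFANet, dict]:
    """Rebuild a model from :func:`save_checkpoint` output."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path) as npz:
        meta = yaml.safe_load(io.BytesIO(npz["__meta__"].tobytes()))
        state = {k[len("state/"):]: npz[k] for k in npz.files if k.startswith("state/")}
    config = NetworkConfig.from_dict(meta["config"])
    model = CFANet(config)
    model.load_state_dict(state, strict=True)
    return model, meta
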