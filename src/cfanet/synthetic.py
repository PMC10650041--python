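"""Seeded generator of small-target segmentation fixtures.

Emulates the difficulty regime of small-lesion slices: elliptical foreground
targets covering under 1% of the image, low contrast against a textured
background (smoothed noise + sinusoidal bands) with bright distractor blobs,
and volumes in which only a small fraction of slices contain any foreground.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = ["SceneConfig", "SamplePair", "generate_sample", "generate_volume",
           "generate_dataset", "load_sample"]


@dataclass
class SamplePair:
    """An image with its aligned binary mask and pixel spacing (mm)."""

    image: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape[:2]:
            raise ValueError(
                f"image shape {self.image.shape} and mask shape "
                f"{self.mask.shape} are not aligned"
            )


@dataclass
class SceneConfig:
    """Knobs of the synthetic small-target scene generator."""

    image_size: int = 128
    n_targets: tuple[int, int] = (1, 2)
    target_radius: tuple[float, float] = (4.0, 7.0)
    max_foreground_fraction: float = 0.01
    contrast: float = 0.7
    background_smoothness: float = 6.0
    background_noise_scale: float = 0.25
    texture_amplitude: float = 0.15
    n_distractors: int = 4
    positive_slice_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.max_foreground_fraction < 0.5:
            raise ValueError(
                f"max_foreground_fraction must be in (0, 0.5), "
                f"got {self.max_foreground_fraction}"
            )
        if self.target_radius[0] < 1.0:
            raise ValueError(f"target radii must be >= 1 px, got {self.target_radius}")
        if not 0.0 <= self.positive_slice_fraction <= 1.0:
            raise ValueError("positive_slice_fraction must be in [0, 1]")


def _ellipse_mask(size: int, center, axes, angle, grid) -> np.ndarray:
    yy, xx = grid
    cy, cx = center
    a, b = axes
    ca, sa = np.cos(angle), np.sin(angle)
    u = (yy - cy) * ca + (xx - cx) * sa
    v = -(yy - cy) * sa + (xx - cx) * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    size = cfg.image_size
    noise = rng.standard_normal((size, size))
    bg = gaussian_filter(noise, cfg.background_smoothness)
    std = bg.std()
    if std > 0:
        bg = bg / std * cfg.background_noise_scale
    yy, xx = np.mgrid[0:size, 0:size] / size
    theta = rng.uniform(0, np.pi)
    freq = rng.uniform(2.0, 6.0)
    phase = rng.uniform(0, 2 * np.pi)
    bg = bg + cfg.texture_amplitude * np.sin(
        2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)) + phase
    )
    return bg + 0.5


def generate_sample(config: SceneConfig, rng: np.random.Generator | None = None,
                    force_empty: bool = False, max_retries: int = 50) -> SamplePair:
    """Draw one image/mask pair honouring the foreground-fraction bound.

    Target placement is rejection-sampled: if a draw cannot satisfy
    ``max_foreground_fraction`` within ``max_retries`` attempts the
    configuration is reported as infeasible.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    size = config.image_size
    image = _background(config, rng)
    grid = np.mgrid[0:size, 0:size].astype(np.float64)

    # bright distractor blobs: similar intensity to targets, different shape
    for _ in range(config.n_distractors):
        cy, cx = rng.uniform(0, size, 2)
        sigma = rng.uniform(2.0, 6.0)
        amp = rng.uniform(0.5, 1.0) * config.contrast
        d2 = (grid[0] - cy) ** 2 + (grid[1] - cx) ** 2
        image = image + amp * np.exp(-d2 / (2 * sigma**2))

    mask = np.zeros((size, size), dtype=np.uint8)
    lo, hi = config.n_targets
    n_targets = 0 if force_empty else int(rng.integers(lo, hi + 1))
    budget = config.max_foreground_fraction * size * size
    for k in range(n_targets):
        placed = False
        for _attempt in range(max_retries):
            a = rng.uniform(*config.target_radius)
            b = rng.uniform(*config.target_radius)
            angle = rng.uniform(0, np.pi)
            margin = max(a, b) + 1
            cy = rng.uniform(margin, size - margin)
            cx = rng.uniform(margin, size - margin)
            ell = _ellipse_mask(size, (cy, cx), (a, b), angle, grid)
            candidate = np.logical_or(mask > 0, ell)
            if candidate.sum() <= budget:
                mask = candidate.astype(np.uint8)
                placed = True
                break
        if not placed:
            if k == 0:
                raise ValueError(
                    "infeasible scene config: cannot place a target of radius "
                    f"{config.target_radius} within foreground fraction "
                    f"{config.max_foreground_fraction} after {max_retries} retries"
                )
            break  # budget exhausted; keep the targets already placed
    image = image + config.contrast * mask
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return SamplePair(image=image, mask=mask)


def generate_volume(config: SceneConfig, n_slices: int = 20) -> list[SamplePair]:
    """An ordered slice stack where only ~``positive_slice_fraction`` of
    slices contain foreground."""
    if n_slices < 20:
        raise ValueError(f"a volume needs at least 20 slices, got {n_slices}")
    rng = np.random.default_rng(config.seed)
    n_positive = int(round(config.positive_slice_fraction * n_slices))
    positive_idx = set(
        rng.choice(n_slices, size=n_positive, replace=False).tolist()
    ) if n_positive else set()
    return [
        generate_sample(config, rng, force_empty=(i not in positive_idx))
        for i in range(n_slices)
    ]


def _to_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)


def load_sample(image_path, mask_path, spacing=(1.0, 1.0)) -> SamplePair:
    """Read an image/mask pair written by :func:`generate_dataset`."""
    img = np.asarray(Image.open(image_path).convert("L"), dtype=np.float32) / 255.0
    mask = (np.asarray(Image.open(mask_path).convert("L")) > 127).astype(np.uint8)
    return SamplePair(image=img, mask=mask, spacing=spacing)


def generate_dataset(config: SceneConfig, n_samples: int, out_dir) -> pd.DataFrame:
    """Write ``n_samples`` PNG pairs plus a manifest CSV; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(n_samples):
        sample = generate_sample(config, rng)
        img_path = out_dir / f"sample_{i:04d}_image.png"
        mask_path = out_dir / f"sample_{i:04d}_mask.png"
        Image.fromarray(_to_uint8(sample.image)).save(img_path)
        Image.fromarray(sample.mask * np.uint8(255)).save(mask_path)
        rows.append({
            "index": i,
            "image": img_path.name,
            "mask": mask_path.name,
            "seed": config.seed,
            "foreground_fraction": float(sample.mask.mean()),
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
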