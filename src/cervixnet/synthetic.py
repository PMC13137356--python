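"""Seeded generator of cervigram-like phantoms with ground truth.

Real cervigram collections are access-restricted, so every stage of the
pipeline is exercised on synthetic phantoms that reproduce the properties
the method actually exploits:

* the **healthy** class is a smooth, texture-free background (an intensity
  plane plus a low-frequency ripple) with an empty lesion mask;
* the **cancer** class adds an oriented sinusoidal texture confined to an
  elliptical lesion; the ground-truth mask is exactly that ellipse;
* **impulse (salt-and-pepper) noise** is applied last — each pixel is
  independently forced to 0 or 255 with probability p/2 each — because the
  directional trimmed statistics of the denoising stage target impulses.

Default geometry is 128x128 with lesions covering roughly 10-20% of the
frame; the texture carrier wavelength (8 px) matches the Gabor bank's
default so the lesion lights up in the fused texture-energy map.  All
randomness flows from the spec seed: identical specs give bit-identical
images.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import save_image, save_mask

HEALTHY, CANCER = "healthy", "cancer"


@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]    # semi-axes (a along rows pre-rotation, b along cols)
    angle_deg: float = 0.0


@dataclass(frozen=True)
class Texture:
    wavelength: float = 8.0
    orientation_deg: float = 0.0  # wave-vector angle, x=cols, y=rows(down)
    amplitude: float = 60.0


@dataclass(frozen=True)
class Background:
    base: float = 110.0
    grad: tuple[float, float] = (20.0, 15.0)  # intensity change across (rows, cols)
    ripple_amp: float = 8.0
    ripple_period: float = 64.0
    ripple_phase: float = 0.0


@dataclass(frozen=True)
class SyntheticSpec:
    size: tuple[int, int] = (128, 128)
    label: str = HEALTHY
    lesion: Ellipse | None = None
    texture: Texture = field(default_factory=Texture)
    background: Background = field(default_factory=Background)
    noise_p: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.label not in (HEALTHY, CANCER):
            raise ValueError(f"unknown label {self.label!r}")
        if not 0.0 <= self.noise_p <= 1.0:
            raise ValueError("noise_p must lie in [0, 1]")
        if self.label == CANCER:
            if self.lesion is None:
                raise ValueError("cancer spec requires a lesion ellipse")
            r, c = self.lesion.center
            reach = max(self.lesion.axes)
            h, w = self.size
            if min(r, c) - reach < 0 or r + reach >= h or c + reach >= w:
                raise ValueError("lesion ellipse must lie entirely inside the image")
            if min(self.lesion.axes) <= 0:
                raise ValueError("lesion axes must be positive")


def _ellipse_mask(size: tuple[int, int], e: Ellipse) -> np.ndarray:
    yy, xx = np.mgrid[: size[0], : size[1]].astype(np.float64)
    y = yy - e.center[0]
    x = xx - e.center[1]
    th = np.deg2rad(e.angle_deg)
    u = y * np.cos(th) + x * np.sin(th)
    v = -y * np.sin(th) + x * np.cos(th)
    return ((u / e.axes[0]) ** 2 + (v / e.axes[1]) ** 2 <= 1.0).astype(np.uint8)


def generate(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, str]:
    """Render one phantom: (uint8 image, {0,1} lesion mask, label)."""
    spec.validate()
    h, w = spec.size
    yy, xx = np.mgrid[:h, :w].astype(np.float64)

    bg = spec.background
    img = (
        bg.base
        + bg.grad[0] * (yy / h - 0.5)
        + bg.grad[1] * (xx / w - 0.5)
        + bg.ripple_amp * np.sin(2.0 * np.pi * (yy + xx) / bg.ripple_period + bg.ripple_phase)
    )

    if spec.label == CANCER:
        mask = _ellipse_mask(spec.size, spec.lesion)
        t = spec.texture
        th = np.deg2rad(t.orientation_deg)
        phase = 2.0 * np.pi * (xx * np.cos(th) + yy * np.sin(th)) / t.wavelength
        img = img + mask * t.amplitude * np.sin(phase)
    else:
        mask = np.zeros(spec.size, dtype=np.uint8)

    img = np.rint(np.clip(img, 0.0, 255.0)).astype(np.uint8)

    if spec.noise_p > 0:
        rng = np.random.default_rng(spec.seed)
        u = rng.random(spec.size)
        img = img.copy()
        img[u < spec.noise_p / 2.0] = 0
        img[u > 1.0 - spec.noise_p / 2.0] = 255
    return img, mask, spec.label


def make_specs(
    n_per_class: int,
    seed: int,
    size: tuple[int, int] = (128, 128),
    noise_p: float = 0.05,
) -> list[SyntheticSpec]:
    """Jittered healthy/cancer spec pairs (lesion pose, texture orientation,
    background slope all drawn from seeded ranges); deterministic in seed."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = size
    specs: list[SyntheticSpec] = []
    for _ in range(n_per_class):
        for label in (HEALTHY, CANCER):
            bg = Background(
                base=float(rng.uniform(95, 125)),
                grad=(float(rng.uniform(-40, 40)), float(rng.uniform(-40, 40))),
                ripple_amp=float(rng.uniform(4, 12)),
                ripple_period=float(rng.uniform(48, 96)),
                ripple_phase=float(rng.uniform(0, 2 * np.pi)),
            )
            lesion = None
            if label == CANCER:
                a = float(rng.uniform(0.19, 0.27) * h)
                b = float(rng.uniform(0.14, 0.20) * w)
                reach = max(a, b) + 2
                lesion = Ellipse(
                    center=(float(rng.uniform(reach, h - 1 - reach)),
                            float(rng.uniform(reach, w - 1 - reach))),
                    axes=(a, b),
                    angle_deg=float(rng.uniform(0, 180)),
                )
            texture = Texture(
                wavelength=8.0,
                orientation_deg=float(rng.uniform(-90, 90)),
                amplitude=float(rng.uniform(50, 70)),
            )
            specs.append(
                SyntheticSpec(
                    size=size,
                    label=label,
                    lesion=lesion,
                    texture=texture,
                    background=bg,
                    noise_p=noise_p,
                    seed=int(rng.integers(2**31)),
                )
            )
    return specs


def generate_dataset(
    out_dir: str | os.PathLike,
    n_per_class: int,
    seed: int,
    size: tuple[int, int] = (128, 128),
    noise_p: float = 0.05,
) -> pd.DataFrame:
    """Write images, masks and a manifest CSV; returns the manifest."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, spec in enumerate(make_specs(n_per_class, seed, size=size, noise_p=noise_p)):
        img, mask, label = generate(spec)
        img_path = os.path.join(out_dir, f"img_{i:04d}.png")
        mask_path = os.path.join(out_dir, f"mask_{i:04d}.png")
        save_image(img_path, img)
        save_mask(mask_path, mask)
        rows.append({"path": img_path, "label": label, "mask_path": mask_path})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
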