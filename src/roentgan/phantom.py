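"""Synthetic knee-like radiograph phantoms.

The phantoms are deliberately simple geometry — two horizontal "bone" bands
separated by a joint gap, a lateral fibula marker, bright osteophyte bumps at
the band edges — but they carry the statistical structure the pipeline cares
about: two severity classes that differ in joint-space width and osteophyte
load, left/right mirror orientation, occasional intensity-inverted negatives,
a continuum of focus levels (Gaussian blur sigma) and rare bright-scratch
artifacts. Every image is a deterministic function of its parameters and seed,
so preprocessing decisions can be checked against ground truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["PhantomParams", "CohortMix", "generate_phantom", "generate_cohort"]

# Class B (the severe class) narrows the joint gap and doubles osteophytes.
CLASS_B_GAP_FACTOR = 0.4
CLASS_B_OSTEOPHYTE_FACTOR = 2


@dataclass(frozen=True)
class PhantomParams:
    """Parameters for a single synthetic radiograph."""

    image_size: int = 299
    class_label: str = "A"
    joint_gap: float = 24.0
    osteophyte_count: int = 2
    blur_sigma: float = 0.0
    invert: bool = False
    laterality: str = "left"
    artifact: bool = False
    noise_sd: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not self.joint_gap < self.image_size / 4:
            raise ValueError("joint_gap must be < image_size/4")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.osteophyte_count < 0:
            raise ValueError("osteophyte_count must be >= 0")
        if self.class_label not in ("A", "B"):
            raise ValueError("class_label must be 'A' or 'B'")
        if self.laterality not in ("left", "right"):
            raise ValueError("laterality must be 'left' or 'right'")


def class_params(class_label: str, base: PhantomParams | None = None,
                 seed: int = 0) -> PhantomParams:
    """Class-typical parameters: B narrows the gap and doubles osteophytes."""
    base = base or PhantomParams()
    if class_label == "A":
        return replace(base, class_label="A", seed=seed)
    return replace(
        base,
        class_label="B",
        joint_gap=base.joint_gap * CLASS_B_GAP_FACTOR,
        osteophyte_count=base.osteophyte_count * CLASS_B_OSTEOPHYTE_FACTOR,
        seed=seed,
    )


def _draw_geometry(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    """Draw the canonical (left-oriented) noiseless phantom, float64 [0, 255]."""
    s = params.image_size
    img = np.full((s, s), 28.0)
    yy, xx = np.mgrid[0:s, 0:s]

    mid = s / 2.0
    half_gap = params.joint_gap / 2.0
    band_depth = 0.32 * s

    # soft-edged bone bands (femur above, tibia below)
    upper = (yy >= mid - half_gap - band_depth) & (yy < mid - half_gap)
    lower = (yy >= mid + half_gap) & (yy < mid + half_gap + band_depth)
    margin = int(round(0.12 * s))
    shaft = (xx >= margin) & (xx < s - margin)
    img[upper & shaft] = 185.0
    img[lower & shaft] = 185.0

    # fibula: a thin secondary shaft on the lateral (left) side, lower half
    fib_lo = margin + int(round(0.02 * s))
    fib_hi = fib_lo + max(2, int(round(0.04 * s)))
    fibula = (xx >= fib_lo) & (xx < fib_hi) & (yy >= mid + half_gap + band_depth)
    img[fibula] = 150.0

    # osteophytes: bright semicircular bumps at the joint-facing band edges
    radius = max(2.0, 0.015 * s)
    for k in range(params.osteophyte_count):
        cx = rng.uniform(margin + radius, s - margin - radius)
        top = bool(rng.integers(0, 2))
        cy = (mid - half_gap) if top else (mid + half_gap)
        bump = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
        img[bump] = 235.0
    return img


def generate_phantom(params: PhantomParams) -> np.ndarray:
    """Render one phantom as an 8-bit grayscale array, deterministically.

    The image is built in canonical left orientation (geometry, blur,
    inversion, noise and artifact all drawn in that frame) and mirrored as the
    final step when ``laterality == 'right'``, so left/right twins at the same
    seed are exact mirror images.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    img = _draw_geometry(params, rng)

    if params.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, params.blur_sigma, mode="reflect")
    if params.invert:
        img = 255.0 - img
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    if params.artifact:
        # one-pixel-wide bright scratch line at a seeded column
        col = int(rng.integers(params.image_size // 4, 3 * params.image_size // 4))
        img[:, col] = 255.0
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if params.laterality == "right":
        img = img[:, ::-1]
    return img


@dataclass(frozen=True)
class CohortMix:
    """Fractions of the cohort carrying each nuisance property."""

    inverted: float = 0.0
    right: float = 0.0
    blurred: float = 0.0
    artifact: float = 0.0
    blur_sigma: float = 4.0

    def validate(self) -> None:
        for name in ("inverted", "right", "blurred", "artifact"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {name} must be in [0, 1]")


MANIFEST_COLUMNS = ["path", "class", "laterality", "inverted", "blur_sigma",
                    "artifact", "split"]


def generate_cohort(n_per_class: int, mix: CohortMix | None = None, seed: int = 0,
                    out_dir: str | os.PathLike | None = None,
                    image_size: int = 299,
                    base: PhantomParams | None = None):
    """Generate a two-class phantom cohort with ground-truth manifest.

    Returns ``(manifest, images)``; if ``out_dir`` is given the images are
    written as PNG and a ``manifest.csv`` alongside them, with manifest paths
    pointing at the files.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    mix = mix or CohortMix()
    mix.validate()
    if base is None:
        # joint gap scales with the canvas (~8% of its side)
        base = PhantomParams(image_size=image_size,
                             joint_gap=round(0.08 * image_size, 1))

    rng = np.random.default_rng(seed)
    rows, images = [], []
    idx = 0
    for label in ("A", "B"):
        for _ in range(n_per_class):
            inverted = bool(rng.random() < mix.inverted)
            right = bool(rng.random() < mix.right)
            blurred = bool(rng.random() < mix.blurred)
            artifact = bool(rng.random() < mix.artifact)
            sigma = mix.blur_sigma if blurred else 0.0
            item_seed = int(rng.integers(0, 2 ** 31))
            params = replace(
                class_params(label, base=base, seed=item_seed),
                blur_sigma=sigma,
                invert=inverted,
                laterality="right" if right else "left",
                artifact=artifact,
            )
            images.append(generate_phantom(params))
            rows.append({
                "path": f"phantom_{idx:05d}.png",
                "class": label,
                "laterality": params.laterality,
                "inverted": inverted,
                "blur_sigma": sigma,
                "artifact": artifact,
                "split": "train",
            })
            idx += 1
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)

    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        for row, img in zip(rows, images):
            path = os.path.join(out_dir, row["path"])
            iio.imwrite(path, img)
        manifest = manifest.assign(
            path=[os.path.join(out_dir, r["path"]) for r in rows])
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest, images
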