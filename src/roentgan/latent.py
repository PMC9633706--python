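"""Latent-space exploration: single-dimension sweeps and linear interpolation.

The generator's input domain is a standard-normal latent space (50-dim by
default); sweeping one coordinate over [−4.2, +4.2] spans ±4.2 standard
deviations of its prior, and linear interpolation between two latent vectors
morphs one generated image into another.
"""

from __future__ import annotations

import numpy as np

from .nn import Sequential

__all__ = [
    "sweep_latents", "interpolate_latents", "perturb_dimension", "interpolate",
    "montage",
]


def _check_latent(z) -> np.ndarray:
    z = np.asarray(z, dtype=np.float32).ravel()
    if not np.isfinite(z).all():
        raise ValueError("latent vector must be finite")
    return z


def sweep_latents(z, dim: int, lo: float = -4.2, hi: float = 4.2,
                  steps: int = 7) -> np.ndarray:
    """Copies of z with coordinate ``dim`` set to evenly spaced values in [lo, hi]."""
    z = _check_latent(z)
    if not 0 <= dim < z.size:
        raise IndexError(f"latent dimension {dim} out of range [0, {z.size})")
    if steps < 2:
        raise ValueError("steps must be >= 2")
    values = np.linspace(lo, hi, steps, dtype=np.float32)
    out = np.tile(z, (steps, 1))
    out[:, dim] = values
    return out


def interpolate_latents(z_a, z_b, steps: int = 7) -> np.ndarray:
    """Latents at (1−α)·z_a + α·z_b for α evenly spaced in [0, 1].

    The endpoint rows are exactly z_a and z_b (no floating-point drift), so
    the end images of the strip reproduce the originals bit-exactly.
    """
    z_a, z_b = _check_latent(z_a), _check_latent(z_b)
    if z_a.size != z_b.size:
        raise ValueError("latent vectors must have the same length")
    if steps < 2:
        raise ValueError("steps must be >= 2")
    alphas = np.linspace(0.0, 1.0, steps, dtype=np.float32)[:, None]
    return (1.0 - alphas) * z_a + alphas * z_b


def perturb_dimension(generator: Sequential, z, dim: int, lo: float = -4.2,
                      hi: float = 4.2, steps: int = 7) -> np.ndarray:
    """Render the image strip of a single-dimension sweep."""
    latents = sweep_latents(z, dim, lo=lo, hi=hi, steps=steps)
    return generator.forward(latents, training=False)


def interpolate(generator: Sequential, z_a, z_b, steps: int = 7) -> np.ndarray:
    """Render the image strip of a linear latent interpolation."""
    latents = interpolate_latents(z_a, z_b, steps=steps)
    return generator.forward(latents, training=False)


def montage(strip: np.ndarray) -> np.ndarray:
    """Lay an (n, H, W, 1) strip out as a single horizontal (H, n·W) image."""
    imgs = np.asarray(strip)
    if imgs.ndim == 4:
        imgs = imgs[..., 0]
    return np.concatenate(list(imgs), axis=1)
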