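"""Synthetic phantoms and noise models for testing the denoiser end to end.

The phantoms emulate the regimes that matter for chequerboard training:

* ``blobs`` — randomly placed Gaussian bumps on a dark background, the
  fluorescence-microscopy-like case (smooth, sparse, locally similar pixels);
* ``ramp`` — a linear gradient, the smoothest possible signal;
* ``sinusoid`` — a separable low-frequency sine pattern;
* ``chequer_texture`` — a pixel-scale alternating pattern, an adversarial
  control where adjacent pixels are maximally dissimilar and the
  neighbour-similarity assumption underlying the method breaks down.

Noise follows the standard microscopy model: additive Gaussian read noise
and/or Poisson shot noise.  Noise is parameterized on the phantom's native
intensity scale (sigma 25 on a 0-255 phantom means 25 grey levels) and is
never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .image_io import Image2D

__all__ = [
    "Phantom",
    "NoisyRealization",
    "make_phantom",
    "add_gaussian_noise",
    "add_poisson_noise",
    "add_mixed_noise",
]

PHANTOM_KINDS = ("blobs", "ramp", "sinusoid", "chequer_texture")


@dataclass
class Phantom:
    """A clean ground-truth image s with its generator provenance."""

    clean: Image2D
    kind: str
    params: dict
    seed: int


@dataclass
class NoisyRealization:
    """One noisy observation x = s + n of a clean image."""

    noisy: Image2D
    noise_kind: str
    sigma: float = 0.0
    gain: float = 0.0
    seed: int = 0
    clean: Optional[Image2D] = field(default=None, repr=False)

    @property
    def noise(self) -> np.ndarray:
        if self.clean is None:
            raise ValueError("clean reference not stored with this realization")
        return self.noisy.pixels - self.clean.pixels


def make_phantom(kind: str, size: tuple = (96, 96), params: Optional[dict] = None,
                 seed: int = 0) -> Phantom:
    """Generate a clean phantom on the [0, high] intensity scale (default 0-255).

    ``params`` accepts ``high`` (intensity ceiling, default 255), and per kind:
    ``n_blobs`` / ``blob_sigma`` / ``background`` for blobs, ``axis`` for the
    ramp, ``period`` for the sinusoid, ``low`` for chequer_texture.
    """
    if kind not in PHANTOM_KINDS:
        raise ValueError(f"unknown phantom kind {kind!r}; expected {PHANTOM_KINDS}")
    m, n = size
    if m < 16 or n < 16:
        raise ValueError(f"phantom size {size} too small; need at least 16x16")
    params = dict(params or {})
    high = float(params.setdefault("high", 255.0))
    rng = np.random.default_rng(seed)
    ii, jj = np.meshgrid(np.arange(m), np.arange(n), indexing="ij")

    if kind == "blobs":
        n_blobs = int(params.setdefault("n_blobs", max(4, (m * n) // 1000)))
        blob_sigma = float(params.setdefault("blob_sigma", min(m, n) / 12.0))
        background = float(params.setdefault("background", 0.05 * high))
        img = np.full((m, n), background)
        for _ in range(n_blobs):
            ci = rng.uniform(0, m)
            cj = rng.uniform(0, n)
            amp = rng.uniform(0.3, 1.0) * (high - background)
            width = blob_sigma * rng.uniform(0.6, 1.4)
            img += amp * np.exp(-((ii - ci) ** 2 + (jj - cj) ** 2) / (2 * width**2))
        img = np.clip(img, 0.0, high)
    elif kind == "ramp":
        axis = params.setdefault("axis", "j")
        t = jj / (n - 1) if axis == "j" else ii / (m - 1)
        img = high * t
    elif kind == "sinusoid":
        period = float(params.setdefault("period", float(min(m, n))))
        img = (high / 4.0) * (
            2.0
            + np.sin(2 * np.pi * ii / period)
            + np.sin(2 * np.pi * jj / period)
        ) / 1.0
        img = (img - img.min()) / (img.max() - img.min()) * high
    else:  # chequer_texture: pixel-scale alternation, the adversarial control
        low = float(params.setdefault("low", 0.1 * high))
        img = np.where((ii + jj) % 2 == 0, high, low).astype(np.float64)

    return Phantom(clean=Image2D(img), kind=kind, params=params, seed=seed)


def add_gaussian_noise(img: Image2D, sigma: float, seed: int = 0) -> NoisyRealization:
    """Add zero-mean Gaussian noise of standard deviation ``sigma`` (intensity
    units).  The result is not clipped, so values may leave the nominal range."""
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=img.pixels.shape)
    return NoisyRealization(
        noisy=Image2D(img.pixels + noise, source_dtype=img.source_dtype,
                      channel_index=img.channel_index, frame_index=img.frame_index),
        noise_kind="gaussian", sigma=float(sigma), seed=seed, clean=img,
    )


def add_poisson_noise(img: Image2D, gain: float, seed: int = 0) -> NoisyRealization:
    """Poisson shot noise: counts drawn at rate clean*gain, rescaled by 1/gain,
    so the per-pixel variance is clean/gain."""
    if not gain > 0:
        raise ValueError(f"gain must be positive, got {gain}")
    if np.any(img.pixels < 0):
        raise ValueError("Poisson noise requires non-negative clean intensities")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(img.pixels * gain).astype(np.float64) / gain
    return NoisyRealization(
        noisy=Image2D(noisy, source_dtype=img.source_dtype,
                      channel_index=img.channel_index, frame_index=img.frame_index),
        noise_kind="poisson", gain=float(gain), seed=seed, clean=img,
    )


def add_mixed_noise(img: Image2D, sigma: float, gain: float,
                    seed: int = 0) -> NoisyRealization:
    """Poisson shot noise followed by additive Gaussian read noise — the usual
    confocal noise model."""
    shot = add_poisson_noise(img, gain, seed=seed)
    read = add_gaussian_noise(shot.noisy, sigma, seed=seed + 1)
    return NoisyRealization(
        noisy=read.noisy, noise_kind="mixed", sigma=float(sigma),
        gain=float(gain), seed=seed, clean=img,
    )
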