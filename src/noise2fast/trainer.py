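"""Training loop primitives: BCE loss, single Adam steps, validation, traces.

The training scheme is Noise2Noise on the four chequerboard pairs: each
iteration feeds one pair (batch size 1), computes binary cross-entropy
between the network output and the complementary downsample, and takes one
Adam step.  Because the four-image set is tiny the network inevitably
overfits it — but the distorted downsamples look nothing like the original
image at a local level, so the original noisy image acts as held-out
validation data: training stops where f(x) most resembles x, and the best
checkpoint by that score is returned.

The heavy lifting (the loop itself) lives in :class:`noise2fast.Noise2Fast`;
:func:`denoise` and :func:`denoise_split` below are thin wrappers over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .chequerboard import TrainingPair, downsample_left, downsample_up
from .image_io import Image2D, NormalizedImage
from .metrics import psnr
from .model import AdamOptimizer, Network, NetworkConfig

__all__ = [
    "TrainerConfig",
    "TrainingTrace",
    "DenoiseResult",
    "bce_loss",
    "train_step",
    "validate",
    "exact_correction_targets",
    "denoise",
    "denoise_split",
]

_BCE_EPS = 1e-7


@dataclass(frozen=True)
class TrainerConfig:
    """Optimization hyperparameters.

    batch_size is fixed at 1 — the four training images are fed one by one.
    """

    learning_rate: float = 0.001
    batch_size: int = 1
    max_iterations: int = 30_000
    validation_interval: int = 100
    patience: int = 10
    seed: int = 0
    pair_sampling: str = "uniform_random"

    def __post_init__(self) -> None:
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size != 1:
            raise ValueError("batch_size is fixed at 1")
        if self.max_iterations < self.validation_interval:
            raise ValueError("max_iterations must cover at least one validation")
        if self.patience < 1:
            raise ValueError("patience must be at least 1")
        if self.pair_sampling not in ("uniform_random", "cyclic"):
            raise ValueError(f"unknown pair_sampling {self.pair_sampling!r}")


@dataclass
class TrainingTrace:
    """Per-iteration loss and per-validation PSNR-to-noisy-input records."""

    losses: list = field(default_factory=list)
    validation_psnrs: list = field(default_factory=list)  # (iteration, psnr_db)
    best_iteration: int = 0
    stopped_reason: str = "max_iterations"


@dataclass
class DenoiseResult:
    denoised: Image2D
    trace: TrainingTrace


def bce_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean binary cross-entropy with predictions clamped to [1e-7, 1 - 1e-7]."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = np.clip(pred, _BCE_EPS, 1.0 - _BCE_EPS)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log1p(-p)))


def train_step(net: Network, pair: TrainingPair, optimizer: AdamOptimizer) -> float:
    """One Adam update on one pair; returns the pre-update loss.

    The gradient is taken at the logits ((p - t) / N), the numerically stable
    formulation of BCE-through-sigmoid.
    """
    pred = net.forward(pair.input_img, train=True)
    target = np.asarray(pair.target_img, dtype=np.float32)
    loss = bce_loss(pred, target)
    if not np.isfinite(loss):
        raise FloatingPointError(
            f"non-finite training loss at pair {pair.tag!r}: {loss}"
        )
    grad_logits = (pred - target) / np.float32(target.size)
    net.backward_logits(grad_logits)
    optimizer.step(net.gradients())
    return loss


def validate(net: Network, x_norm: NormalizedImage) -> float:
    """Validation PSNR: how closely f(x) maps the noisy image to itself.

    Computed in normalized space with data range 1, so it is invariant to the
    stored intensity offset and scale.
    """
    out = net.forward(np.asarray(x_norm.pixels, dtype=np.float32))
    return psnr(out, x_norm.pixels, data_range=1.0)


def exact_correction_targets(
    pairs: list[TrainingPair],
    clean: Image2D,
    affine: Optional[NormalizedImage] = None,
) -> list[TrainingPair]:
    """Replace each target t for a mapping a -> b by t - (s_b - s_a).

    ``clean`` is the known ground-truth signal for the same image; the
    correction removes the signal-offset term that chequerboard pairing
    introduces on top of pure Noise2Noise.  The clean image is mapped through
    the same affine normalization as the noisy one (``affine``; its own
    min-max if not given) — only the scale matters, since the offset cancels
    in the difference.  Corrected targets are clamped to [0, 1] for BCE
    validity.
    """
    if affine is not None:
        s = (clean.pixels - affine.offset) / affine.scale
    else:
        lo, hi = float(clean.pixels.min()), float(clean.pixels.max())
        s = (clean.pixels - lo) / (hi - lo) if hi > lo else np.zeros_like(clean.pixels)

    s_up_even, s_up_odd = downsample_up(s)
    s_left_even, s_left_odd = downsample_left(s)
    clean_ds = {
        "up_even": s_up_even,
        "up_odd": s_up_odd,
        "left_even": s_left_even,
        "left_odd": s_left_odd,
    }
    corrected = []
    for pair in pairs:
        a_name, b_name = pair.tag.split("->")
        if a_name not in clean_ds or b_name not in clean_ds:
            raise ValueError(f"pair tag {pair.tag!r} is not a chequerboard mapping")
        s_a, s_b = clean_ds[a_name], clean_ds[b_name]
        if s_b.shape != pair.target_img.shape:
            raise ValueError(
                f"clean image shape mismatch for pair {pair.tag!r}: "
                f"{s_b.shape} vs {pair.target_img.shape}"
            )
        new_target = np.clip(pair.target_img - (s_b - s_a), 0.0, 1.0)
        corrected.append(TrainingPair(pair.input_img, new_target, pair.tag))
    return corrected


def denoise(
    x: Image2D,
    net_cfg: Optional[NetworkConfig] = None,
    cfg: Optional[TrainerConfig] = None,
    monitor=None,
) -> DenoiseResult:
    """Denoise one image plane with the full pipeline (thin wrapper over the
    :class:`noise2fast.Noise2Fast` estimator)."""
    from .estimator import Noise2Fast

    est = Noise2Fast.from_configs(net_cfg, cfg, monitor=monitor)
    est.fit(x)
    return DenoiseResult(denoised=est.denoise(), trace=est.trace_)


def denoise_split(
    x: Image2D,
    net_cfg: Optional[NetworkConfig] = None,
    cfg: Optional[TrainerConfig] = None,
    monitor=None,
) -> DenoiseResult:
    """Ablation variant: denoise the "up" downsamples separately and
    reassemble them, instead of applying the network to the full image."""
    from .estimator import Noise2Fast

    est = Noise2Fast.from_configs(net_cfg, cfg, monitor=monitor, inference="split")
    est.fit(x)
    return DenoiseResult(denoised=est.denoise(), trace=est.trace_)
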