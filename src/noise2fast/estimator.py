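"""The Noise2Fast estimator: a scikit-learn-style zero-shot image denoiser.

``fit(X)`` trains the network on the four chequerboard downsamples of the
single noisy image X, monitoring how closely the network maps X to itself and
keeping the best checkpoint by that validation PSNR.  ``transform(X)`` (or
``denoise()``) applies the best checkpoint and restores the original
intensity scale.  Being zero-shot, the estimator is normally fitted and
applied to the same image: ``Noise2Fast().fit_transform(noisy)``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .chequerboard import (
    block_training_pairs,
    build_training_set,
    downsample_up,
    reassemble_up,
)
from .image_io import Image2D, NormalizedImage, denormalize, normalize
from .model import AdamOptimizer, Network, NetworkConfig
from .trainer import (
    TrainerConfig,
    TrainingTrace,
    train_step,
    validate,
)

__all__ = ["Noise2Fast"]


class Noise2Fast(TransformerMixin, BaseEstimator):
    """Blind zero-shot single-image denoiser.

    Parameters
    ----------
    block_widths : tuple of int, default (32, 64, 128, 256)
        Channel counts of the convolution blocks (each block doubles the
        previous width in the published architecture).
    convs_per_block : int, default 2
        Same-padded 3x3 convolutions (ReLU) per block.
    kernel_size, final_kernel_size : int
        Body and head kernel sizes (3 and 1 in the published architecture).
    learning_rate : float, default 0.001
        Adam learning rate.
    max_iterations : int, default 30000
        Hard cap on single-pair training iterations.
    validation_interval : int, default 100
        Iterations between validation passes on the full noisy image.
    patience : int, default 10
        Validations without a new best PSNR before stopping.
    pair_sampling : {"uniform_random", "cyclic"}
        Order in which the four training pairs are fed.
    training_set : {"chequerboard", "block2", "block3"}
        "chequerboard" uses the four parity-pair images; "block2"/"block3"
        use conventional 2x2 / 3x3 block downsampling (faster, less
        accurate — the ablation mode).
    inference : {"full", "split"}
        "full" applies the trained network to the whole noisy image;
        "split" denoises the two "up" downsamples and reassembles them
        (the ablation variant).
    augment_flips : bool, default False
        Randomly flip each training pair (off by default: the method trains
        on the discrete four-image set as published).
    exact_correction_clean : Image2D, optional
        Ground-truth signal; if given, the signal-offset term s_b - s_a is
        subtracted from every training target (diagnostic "cheat" mode).
    monitor : callable, optional
        Called at every validation as ``monitor(iteration, val_psnr, network,
        estimator)`` — hook for tracking ground-truth PSNR on phantoms.
    random_state : int, default 0
        Seeds weight initialization and pair sampling.

    Attributes
    ----------
    network_ : Network
        The trained network at the best validation checkpoint.
    trace_ : TrainingTrace
        Per-iteration losses, validation PSNRs, best iteration, stop reason.
    n_iter_ : int
        Iterations actually run.
    best_validation_psnr_ : float
        Highest PSNR of f(x) against x observed during training.
    offset_, scale_ : float
        Affine map between raw intensities and the [0, 1] training space.
    """

    def __init__(
        self,
        block_widths=(32, 64, 128, 256),
        convs_per_block: int = 2,
        kernel_size: int = 3,
        final_kernel_size: int = 1,
        learning_rate: float = 0.001,
        max_iterations: int = 30_000,
        validation_interval: int = 100,
        patience: int = 10,
        pair_sampling: str = "uniform_random",
        training_set: str = "chequerboard",
        inference: str = "full",
        augment_flips: bool = False,
        exact_correction_clean: Optional[Image2D] = None,
        monitor=None,
        random_state: int = 0,
    ):
        self.block_widths = block_widths
        self.convs_per_block = convs_per_block
        self.kernel_size = kernel_size
        self.final_kernel_size = final_kernel_size
        self.learning_rate = learning_rate
        self.max_iterations = max_iterations
        self.validation_interval = validation_interval
        self.patience = patience
        self.pair_sampling = pair_sampling
        self.training_set = training_set
        self.inference = inference
        self.augment_flips = augment_flips
        self.exact_correction_clean = exact_correction_clean
        self.monitor = monitor
        self.random_state = random_state

    # -- construction helpers ----------------------------------------------

    @classmethod
    def from_configs(
        cls,
        net_cfg: Optional[NetworkConfig] = None,
        cfg: Optional[TrainerConfig] = None,
        **overrides,
    ) -> "Noise2Fast":
        net_cfg = net_cfg or NetworkConfig()
        cfg = cfg or TrainerConfig()
        return cls(
            block_widths=net_cfg.block_widths,
            convs_per_block=net_cfg.convs_per_block,
            kernel_size=net_cfg.kernel_size,
            final_kernel_size=net_cfg.final_kernel_size,
            learning_rate=cfg.learning_rate,
            max_iterations=cfg.max_iterations,
            validation_interval=cfg.validation_interval,
            patience=cfg.patience,
            pair_sampling=cfg.pair_sampling,
            random_state=cfg.seed,
            **overrides,
        )

    def _network_config(self) -> NetworkConfig:
        return NetworkConfig(
            in_channels=1,
            block_widths=tuple(self.block_widths),
            convs_per_block=self.convs_per_block,
            kernel_size=self.kernel_size,
            final_kernel_size=self.final_kernel_size,
        )

    def _trainer_config(self) -> TrainerConfig:
        return TrainerConfig(
            learning_rate=self.learning_rate,
            max_iterations=self.max_iterations,
            validation_interval=self.validation_interval,
            patience=self.patience,
            seed=self.random_state,
            pair_sampling=self.pair_sampling,
        )

    @staticmethod
    def _as_image(X) -> Image2D:
        if isinstance(X, Image2D):
            return X
        return Image2D(np.asarray(X, dtype=np.float64))

    # -- the training loop ---------------------------------------------------

    def fit(self, X, y=None):
        """Train on the chequerboard pairs of the single noisy image X.

        X may be an :class:`Image2D` or any 2D array-like.  ``y`` is ignored
        (present for scikit-learn API compatibility).
        """
        img = self._as_image(X)
        cfg = self._trainer_config()  # validates hyperparameters
        if self.training_set not in ("chequerboard", "block2", "block3"):
            raise ValueError(f"unknown training_set {self.training_set!r}")
        if self.inference not in ("full", "split"):
            raise ValueError(f"unknown inference {self.inference!r}")

        norm = normalize(img)
        self.norm_ = norm
        self.offset_ = norm.offset
        self.scale_ = norm.scale
        self.input_image_ = img

        if norm.degenerate:
            # a constant image carries no training signal; return it unchanged
            self.network_ = None
            self.trace_ = TrainingTrace(stopped_reason="degenerate_input")
            self.n_iter_ = 0
            self.best_validation_psnr_ = float("nan")
            return self

        if self.training_set == "chequerboard":
            pairs = build_training_set(norm)
        else:
            pairs = block_training_pairs(norm.pixels, k=int(self.training_set[-1]))

        if self.exact_correction_clean is not None:
            from .trainer import exact_correction_targets

            pairs = exact_correction_targets(
                pairs, self.exact_correction_clean, affine=norm
            )

        init_seed, sample_seed = [
            int(s.generate_state(1, np.uint32)[0]) % (2**31)
            for s in np.random.SeedSequence(self.random_state).spawn(2)
        ]
        net = Network(self._network_config(), seed=init_seed)
        optimizer = AdamOptimizer(net.parameters(), lr=cfg.learning_rate)
        rng = np.random.default_rng(sample_seed)

        trace = TrainingTrace()
        best_state = net.get_state()
        best_psnr = -np.inf
        best_iteration = 0
        stale = 0
        stopped = "max_iterations"

        for iteration in range(1, cfg.max_iterations + 1):
            if cfg.pair_sampling == "uniform_random":
                pair = pairs[rng.integers(len(pairs))]
            else:
                pair = pairs[(iteration - 1) % len(pairs)]
            if self.augment_flips:
                flips = rng.integers(2, size=2)
                if flips[0] or flips[1]:
                    sl = tuple(
                        slice(None, None, -1) if f else slice(None) for f in flips
                    )
                    pair = type(pair)(
                        np.ascontiguousarray(pair.input_img[sl]),
                        np.ascontiguousarray(pair.target_img[sl]),
                        pair.tag,
                    )
            loss = train_step(net, pair, optimizer)
            trace.losses.append(loss)

            if iteration % cfg.validation_interval == 0:
                val = validate(net, norm)
                trace.validation_psnrs.append((iteration, val))
                if val > best_psnr:
                    best_psnr = val
                    best_state = net.get_state()
                    best_iteration = iteration
                    stale = 0
                else:
                    stale += 1
                if self.monitor is not None:
                    self.monitor(iteration, val, net, self)
                if stale >= cfg.patience:
                    stopped = "patience"
                    break

        net.set_state(best_state)
        trace.best_iteration = best_iteration
        trace.stopped_reason = stopped
        self.network_ = net
        self.trace_ = trace
        self.n_iter_ = len(trace.losses)
        self.best_validation_psnr_ = float(best_psnr)
        return self

    # -- inference -----------------------------------------------------------

    def transform(self, X) -> np.ndarray:
        """Denoise an image with the fitted network, on the original scale.

        Normally called on the image the estimator was fitted on; other
        images pass through the same affine normalization learned at fit.
        Returns a float64 array of the input's shape.
        """
        if not hasattr(self, "network_"):
            raise RuntimeError("this Noise2Fast instance is not fitted yet")
        img = self._as_image(X)
        if self.network_ is None:  # degenerate constant input
            return img.pixels.copy()
        norm_px = (img.pixels - self.offset_) / self.scale_
        if self.inference == "split":
            up_even, up_odd = downsample_up(norm_px.astype(np.float32))
            out_even = self.network_.forward(up_even)
            out_odd = self.network_.forward(up_odd)
            out = reassemble_up(out_even, out_odd).astype(np.float64)
            # odd widths: the cropped trailing column passes through the
            # full-image forward instead
            if out.shape != norm_px.shape:
                full = self.network_.forward(norm_px.astype(np.float32))
                padded = np.asarray(full, dtype=np.float64)
                padded[:, : out.shape[1]] = out
                out = padded
        else:
            out = np.asarray(
                self.network_.forward(norm_px.astype(np.float32)), dtype=np.float64
            )
        return out * self.scale_ + self.offset_

    def denoise(self, X=None) -> Image2D:
        """Denoise (by default) the image the estimator was fitted on,
        returned as an :class:`Image2D` with the source's provenance."""
        if not hasattr(self, "network_"):
            raise RuntimeError("this Noise2Fast instance is not fitted yet")
        img = self.input_image_ if X is None else self._as_image(X)
        out = self.transform(img)
        return denormalize(self.norm_, (out - self.offset_) / self.scale_)

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.non_deterministic = False
        tags.requires_fit = True
        return tags
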