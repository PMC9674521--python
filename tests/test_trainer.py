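"""Training-loop primitives: loss, steps, validation, stopping, correction."""

import numpy as np
import pytest

from noise2fast import (
    AdamOptimizer,
    Image2D,
    Network,
    NetworkConfig,
    TrainerConfig,
    add_gaussian_noise,
    bce_loss,
    denoise,
    exact_correction_targets,
    make_phantom,
    normalize,
    psnr,
    train_step,
    validate,
)
from noise2fast.chequerboard import TrainingPair, build_training_set
from noise2fast.estimator import Noise2Fast

SMALL_NET = dict(block_widths=(8, 16), convs_per_block=2)


class TestBCELoss:
    def test_half_half_is_ln2(self):
        p = np.full((4, 4), 0.5)
        assert bce_loss(p, p) == pytest.approx(np.log(2), abs=1e-6)

    def test_point_nine_vs_one(self):
        assert bce_loss(np.full((3, 3), 0.9), np.ones((3, 3))) == pytest.approx(
            -np.log(0.9), abs=1e-6
        )

    def test_perfect_prediction_limit(self):
        loss = bce_loss(np.full((3, 3), 1e-7), np.zeros((3, 3)))
        assert 0 <= loss < 1e-6

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros((2, 2)), np.zeros((3, 2)))


class TestTrainStep:
    def _setup(self, seed=0, dtype=np.float32):
        rng = np.random.default_rng(3)
        cfg = NetworkConfig(block_widths=(4, 8))
        net = Network(cfg, seed=seed, dtype=dtype)
        x = rng.random((12, 10)).astype(np.float32)
        pair = TrainingPair(x, np.clip(x + 0.05, 0, 1), "up_even->up_odd")
        return net, pair

    def test_step_changes_weights(self):
        net, pair = self._setup()
        before = net.get_state()
        opt = AdamOptimizer(net.parameters())
        train_step(net, pair, opt)
        assert any(
            not np.array_equal(a, b) for a, b in zip(before, net.parameters())
        )

    def test_identical_seeds_identical_losses(self):
        losses = []
        for _ in range(2):
            net, pair = self._setup(seed=1)
            opt = AdamOptimizer(net.parameters())
            losses.append([train_step(net, pair, opt) for _ in range(20)])
        assert losses[0] == losses[1]

    def test_descent_on_identity_task(self):
        """On a noiseless target=input task the loss drops well below start."""
        rng = np.random.default_rng(5)
        net = Network(NetworkConfig(block_widths=(8,)), seed=2)
        x = rng.random((16, 16)).astype(np.float32)
        pair = TrainingPair(x, x, "up_even->up_odd")
        opt = AdamOptimizer(net.parameters())
        losses = [train_step(net, pair, opt) for _ in range(500)]
        assert losses[-1] < losses[0]


class TestValidate:
    def test_untrained_net_finite_positive(self, rng):
        net = Network(NetworkConfig(block_widths=(4,)), seed=0)
        norm = normalize(Image2D(rng.uniform(0, 255, (16, 16))))
        v = validate(net, norm)
        assert np.isfinite(v) and v > 0

    def test_invariant_to_stored_affine(self, rng):
        from noise2fast.image_io import NormalizedImage

        net = Network(NetworkConfig(block_widths=(4,)), seed=0)
        px = rng.random((16, 16))
        a = NormalizedImage(px, offset=0.0, scale=1.0)
        b = NormalizedImage(px, offset=-500.0, scale=1234.0)
        assert validate(net, a) == validate(net, b)


class TestExactCorrection:
    def test_constant_clean_leaves_targets_unchanged(self, rng):
        noisy = Image2D(rng.uniform(0, 255, (16, 16)))
        norm = normalize(noisy)
        pairs = build_training_set(norm)
        corrected = exact_correction_targets(
            pairs, Image2D(np.full((16, 16), 42.0)), affine=norm
        )
        for p, c in zip(pairs, corrected):
            np.testing.assert_array_equal(p.target_img, c.target_img)

    def test_correction_far_below_noise(self):
        """|s_odd - s_even| of a smooth phantom is much smaller than the
        noise: the term the correction removes is nearly negligible."""
        ph = make_phantom("blobs", (96, 96), seed=0)
        real = add_gaussian_noise(ph.clean, sigma=25.0, seed=0)
        norm = normalize(real.noisy)
        pairs = build_training_set(norm)
        corrected = exact_correction_targets(pairs, ph.clean, affine=norm)
        sigma_norm = 25.0 / norm.scale
        for p, c in zip(pairs, corrected):
            mean_shift = np.abs(p.target_img - c.target_img).mean()
            assert mean_shift < 0.25 * sigma_norm

    def test_shape_mismatch_rejected(self, rng):
        noisy = Image2D(rng.uniform(0, 255, (16, 16)))
        pairs = build_training_set(normalize(noisy))
        with pytest.raises(ValueError):
            exact_correction_targets(pairs, Image2D(np.zeros((20, 20))))


class TestDenoisePipeline:
    def test_constant_image_returned_unchanged(self):
        result = denoise(Image2D(np.full((32, 32), 99.0)))
        assert result.trace.stopped_reason == "degenerate_input"
        assert np.array_equal(result.denoised.pixels, np.full((32, 32), 99.0))
        assert result.trace.losses == []

    def test_early_stopping_and_best_restore(self, noisy_blobs):
        est = Noise2Fast(
            max_iterations=600, validation_interval=50, patience=3,
            random_state=0, **SMALL_NET,
        )
        est.fit(noisy_blobs.noisy)
        trace = est.trace_
        iters, vals = zip(*trace.validation_psnrs)
        best_idx = int(np.argmax(vals))
        assert trace.best_iteration == iters[best_idx]
        if trace.stopped_reason == "patience":
            # none of the validations after the best one beat it
            assert all(v <= vals[best_idx] for v in vals[best_idx + 1 :])
            assert len(vals) - 1 - best_idx >= 3
        # restored network reproduces the best checkpoint's validation PSNR
        assert validate(est.network_, est.norm_) == pytest.approx(
            vals[best_idx], abs=1e-6
        )

    def test_end_to_end_determinism(self, noisy_blobs):
        outs = []
        for _ in range(2):
            result = denoise(
                noisy_blobs.noisy,
                NetworkConfig(**SMALL_NET),
                TrainerConfig(max_iterations=200, validation_interval=50,
                              patience=2, seed=7),
            )
            outs.append(result.denoised.pixels)
        assert np.array_equal(outs[0], outs[1])

    def test_improves_over_noisy_input(self, blobs_phantom, noisy_blobs):
        result = denoise(
            noisy_blobs.noisy,
            NetworkConfig(**SMALL_NET),
            TrainerConfig(max_iterations=1500, validation_interval=100,
                          patience=5, seed=1),
        )
        clean = blobs_phantom.clean.pixels
        assert psnr(result.denoised.pixels, clean, 255.0) > psnr(
            noisy_blobs.noisy.pixels, clean, 255.0
        )


def test_noise2noise_reduction_sanity(blobs_phantom):
    """Training on two independent noisy realizations of the same phantom
    (no downsampling at all) also denoises — the chequerboard scheme rests
    on this pairing principle."""
    clean = blobs_phantom.clean
    r1 = add_gaussian_noise(clean, sigma=25.0, seed=1)
    r2 = add_gaussian_noise(clean, sigma=25.0, seed=2)
    lo = min(r1.noisy.pixels.min(), r2.noisy.pixels.min())
    hi = max(r1.noisy.pixels.max(), r2.noisy.pixels.max())
    x1 = (r1.noisy.pixels - lo) / (hi - lo)
    x2 = (r2.noisy.pixels - lo) / (hi - lo)
    net = Network(NetworkConfig(block_widths=(8, 16)), seed=0)
    opt = AdamOptimizer(net.parameters())
    pair = TrainingPair(x1.astype(np.float32), x2.astype(np.float32), "up_even->up_odd")
    for _ in range(400):
        train_step(net, pair, opt)
    out = np.asarray(net.forward(x1.astype(np.float32)), float) * (hi - lo) + lo
    assert psnr(out, clean.pixels, 255.0) > psnr(r1.noisy.pixels, clean.pixels, 255.0)
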