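# noise2fast

Blind zero-shot denoising of single images by chequerboard downsampling.

Microscopists often face a single noisy image — a low-light live-cell frame,
a fast confocal scan — with no training set, no clean reference and no
estimate of the noise level. This package denoises such an image using only
the image itself: it splits the pixel lattice into its two chequerboard
parity classes, compresses each class into half-size images, trains a small
convolutional network to map each half onto its complement
(a Noise2Noise-style task whose input and target noise are independent), and
applies the trained network to the full image. Because the downsampled
training images are geometrically distorted versions of the input, the
original noisy image doubles as a validation set: training keeps the
checkpoint where the network's output most resembles the noisy input, which
tracks the (unobservable) ground-truth optimum.

The model: for a noisy image `x = s + n` with `m×n` pixels, the "up"
chequerboard downsamples are

    x_even(i,j) = x(i, 2j + (i mod 2)),   x_odd(i,j) = x(i, 2j + ((i+1) mod 2))

(`m × n/2` each), and the "left" pair is the transpose construction
(`m/2 × n`). The four mappings `even ↔ odd` form the whole training set.
The network is 8 same-padded 3×3 ReLU convolutions (widths 32, 32, 64, 64,
128, 128, 256, 256) plus a 1×1 convolution and sigmoid, trained with
binary cross-entropy and Adam (lr 0.001, batch size 1) on min–max
normalized intensities. See `docs/methods.md` for assumptions, parameter
choices and limitations.

The network, backpropagation and Adam are implemented directly in numpy
(im2col + BLAS); the package has no deep-learning framework dependency and
runs on one CPU core.

## Worked example

```python
import numpy as np
from noise2fast import Noise2Fast, make_phantom, add_gaussian_noise, psnr

phantom = make_phantom("blobs", (96, 96), seed=0)        # clean s, 0-255 scale
noisy = add_gaussian_noise(phantom.clean, sigma=25.0, seed=100)  # x = s + n

est = Noise2Fast(block_widths=(32, 64), max_iterations=2000,
                 validation_interval=100, patience=1_000_000, random_state=0)
denoised = est.fit_transform(noisy.noisy.pixels)

print(f"noisy    PSNR: {psnr(noisy.noisy.pixels, phantom.clean.pixels, 255):.2f} dB")
print(f"denoised PSNR: {psnr(denoised, phantom.clean.pixels, 255):.2f} dB")
print(f"best checkpoint: iteration {est.trace_.best_iteration}, "
      f"validation PSNR {est.best_validation_psnr_:.2f} dB")
```

prints

```
noisy    PSNR: 20.16 dB
denoised PSNR: 33.97 dB
best checkpoint: iteration 200, validation PSNR 23.83 dB
```

The noisy input sits at the σ=25 noise floor (≈20 dB against the clean
phantom); the zero-shot denoiser recovers ≈ +14 dB without ever seeing clean
data. The "validation PSNR" is measured against the *noisy* image (its
ceiling is the noise floor in normalized space, here ≈23 dB) — it is a
stopping signal, not a quality score; the checkpoint it selects is what
delivers the 33.97 dB against the hidden ground truth. This example uses the
compact half-width network and fixed 2,000-iteration horizon of the test
suite; for real images the defaults (`Noise2Fast()`) use the full published
architecture with early stopping.

The same pipeline from the shell:

```
noise2fast make-fixture blobs --size 96 96 --sigma 25 --seed 1 --out-prefix demo
noise2fast denoise demo_noisy.tif -o demo_denoised.tif --seed 1
noise2fast evaluate demo_denoised.tif demo_clean.tif
```

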