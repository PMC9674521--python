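"""Chequerboard downsampling: the four-image training set built from one image.

Colour the pixel lattice like a chequerboard by the parity of i + j.  Each
parity class holds half the pixels; compressing a class along the column axis
("up" downsamples, shape m x n/2) or the row axis ("left" downsamples, shape
m/2 x n) yields half-size images whose pixel values are pure subsets of the
original.  Mapping one parity class onto its complement is a Noise2Noise-style
training task in which the noise of input and target are independent, while
the underlying signals differ only by one-pixel offsets.

Conventions
-----------
* 0-based row-major indices; i is the row, j the column.
* "even" collects pixels with (i + j) even, "odd" those with (i + j) odd.
  The odd class is addressed as ``x(i, 2j + ((i+1) mod 2))`` — the parity
  complement of the even class, which stays in range on every row.
* Odd trailing dimensions are cropped before splitting.  Inference always
  runs on the full uncropped image, so no pixels are lost in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import NormalizedImage

__all__ = [
    "DownsampleSet",
    "TrainingPair",
    "downsample_up",
    "downsample_left",
    "reassemble_up",
    "reassemble_left",
    "build_downsample_set",
    "build_training_set",
    "block_downsample",
]

PAIR_TAGS = (
    "up_even->up_odd",
    "up_odd->up_even",
    "left_even->left_odd",
    "left_odd->left_even",
)


@dataclass
class DownsampleSet:
    """The four chequerboard downsamples of one image."""

    up_even: np.ndarray
    up_odd: np.ndarray
    left_even: np.ndarray
    left_odd: np.ndarray
    source_shape: tuple


@dataclass
class TrainingPair:
    """One input->target mapping between complementary downsamples."""

    input_img: np.ndarray
    target_img: np.ndarray
    tag: str

    def __post_init__(self) -> None:
        if self.input_img.shape != self.target_img.shape:
            raise ValueError(
                f"pair {self.tag!r}: input shape {self.input_img.shape} != "
                f"target shape {self.target_img.shape}"
            )
        if not self.tag:
            raise ValueError("pair tag must be a non-empty label")


def _validate(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 2:
        raise ValueError(f"expected a 2D array, got shape {x.shape}")
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError(f"image of shape {x.shape} is too small to downsample")
    return x


def downsample_up(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split into the two parity classes, compressing columns.

    Returns ``(up_even, up_odd)`` of shape ``(m, n//2)``:
    ``up_even[i, k] = x[i, 2k + (i mod 2)]`` and
    ``up_odd[i, k]  = x[i, 2k + ((i+1) mod 2)]``.
    An odd trailing column is cropped first.
    """
    x = _validate(x)
    m, n = x.shape
    x = x[:, : n - (n % 2)]
    even = x[:, ::2].copy()
    odd = x[:, 1::2].copy()
    # on odd rows the parity classes swap columns
    even[1::2], odd[1::2] = x[1::2, 1::2], x[1::2, ::2]
    return even, odd


def downsample_left(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split into the two parity classes, compressing rows.

    Returns ``(left_even, left_odd)`` of shape ``(m//2, n)``:
    ``left_even[k, j] = x[2k + (j mod 2), j]`` and
    ``left_odd[k, j]  = x[2k + ((j+1) mod 2), j]``.
    An odd trailing row is cropped first.
    """
    x = _validate(x)
    even, odd = downsample_up(x.T)
    return even.T, odd.T


def reassemble_up(up_even: np.ndarray, up_odd: np.ndarray) -> np.ndarray:
    """Interleave the two "up" downsamples back into the full image.

    Exact left inverse of :func:`downsample_up` on even-width images.
    """
    up_even = np.asarray(up_even)
    up_odd = np.asarray(up_odd)
    if up_even.shape != up_odd.shape:
        raise ValueError(
            f"shape mismatch: {up_even.shape} vs {up_odd.shape}"
        )
    m, half = up_even.shape
    out = np.empty((m, 2 * half), dtype=np.result_type(up_even, up_odd))
    out[::2, ::2] = up_even[::2]
    out[::2, 1::2] = up_odd[::2]
    out[1::2, 1::2] = up_even[1::2]
    out[1::2, ::2] = up_odd[1::2]
    return out


def reassemble_left(left_even: np.ndarray, left_odd: np.ndarray) -> np.ndarray:
    """Interleave the two "left" downsamples; inverse of :func:`downsample_left`."""
    return reassemble_up(np.asarray(left_even).T, np.asarray(left_odd).T).T


def build_downsample_set(x: np.ndarray) -> DownsampleSet:
    x = _validate(x)
    up_even, up_odd = downsample_up(x)
    left_even, left_odd = downsample_left(x)
    return DownsampleSet(up_even, up_odd, left_even, left_odd, x.shape)


def build_training_set(x: NormalizedImage | np.ndarray) -> list[TrainingPair]:
    """Materialize the discrete four-pair training set of one normalized image.

    The pairs map each downsample to its parity complement:
    up_even->up_odd, up_odd->up_even, left_even->left_odd, left_odd->left_even.
    """
    if isinstance(x, NormalizedImage):
        if x.degenerate:
            raise ValueError("constant (degenerate) image has no training signal")
        px = x.pixels
    else:
        px = np.asarray(x)
    ds = build_downsample_set(px)
    return [
        TrainingPair(ds.up_even, ds.up_odd, PAIR_TAGS[0]),
        TrainingPair(ds.up_odd, ds.up_even, PAIR_TAGS[1]),
        TrainingPair(ds.left_even, ds.left_odd, PAIR_TAGS[2]),
        TrainingPair(ds.left_odd, ds.left_even, PAIR_TAGS[3]),
    ]


def block_downsample(x: np.ndarray, k: int) -> list[np.ndarray]:
    """Conventional k-fold block downsampling (the ablation alternative).

    Divides the image into k x k blocks and collects, for each in-block offset
    (u, v), the image of all pixels at that offset.  Returns the k^2 images in
    row-major offset order; together they partition the cropped source.
    """
    if k not in (2, 3):
        raise ValueError(f"block factor must be 2 or 3, got {k}")
    x = _validate(x)
    m, n = x.shape
    if m < k or n < k:
        raise ValueError(f"image of shape {x.shape} is smaller than a {k}x{k} block")
    x = x[: m - (m % k), : n - (n % k)]
    return [x[u::k, v::k].copy() for u in range(k) for v in range(k)]


def block_training_pairs(x: np.ndarray, k: int) -> list[TrainingPair]:
    """Training pairs for block-downsampling mode: each sub-image is mapped to
    the next one cyclically (all sub-images see the same signal at a small
    offset, with independent noise)."""
    subs = block_downsample(x, k)
    return [
        TrainingPair(subs[t], subs[(t + 1) % len(subs)], f"block{t}->block{(t + 1) % len(subs)}")
        for t in range(len(subs))
    ]
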