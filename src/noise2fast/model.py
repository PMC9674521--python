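"""The small fully convolutional network f_theta, in plain numpy.

The architecture is deliberately tiny: blocks of same-padded 3x3 convolutions
with ReLU, doubling the channel count per block, closed by a 1x1 convolution
and a logistic sigmoid.  No batch normalization, no pooling, no skip
connections — a shallow network with a small receptive field both converges
fast and is slow to memorize the noise, which is exactly what per-image
training needs.

Forward and backward passes are written directly as im2col + GEMM; gradients
are exact (unit-tested against finite differences) and everything is float32,
seeded, and bit-deterministic on one machine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "NetworkConfig",
    "Network",
    "AdamOptimizer",
    "build_network",
    "receptive_field_extent",
]

_EPS = np.float32(1e-7)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    The defaults reproduce the published layout: two 32-channel 3x3
    convolutions with ReLU, repeated three more times doubling the channels
    each block, then a 1x1 convolution and sigmoid.
    """

    in_channels: int = 1
    block_widths: tuple = (32, 64, 128, 256)
    convs_per_block: int = 2
    kernel_size: int = 3
    final_kernel_size: int = 1

    def __post_init__(self) -> None:
        if self.in_channels < 1:
            raise ValueError("in_channels must be positive")
        if not self.block_widths or any(w < 1 for w in self.block_widths):
            raise ValueError("block_widths must be positive integers")
        if self.convs_per_block < 1:
            raise ValueError("convs_per_block must be positive")
        for k in (self.kernel_size, self.final_kernel_size):
            if k < 1 or k % 2 == 0:
                raise ValueError(f"kernel sizes must be odd and positive, got {k}")

    @property
    def receptive_field_extent(self) -> int:
        """Side length of the square receptive field of one output pixel.

        Each same-padded k x k convolution grows the field by k - 1; the body
        has convs_per_block * len(block_widths) of them, plus the final head
        convolution.
        """
        body = (self.kernel_size - 1) * self.convs_per_block * len(self.block_widths)
        head = self.final_kernel_size - 1
        return 1 + body + head

    def layer_channels(self) -> list[tuple]:
        """(cin, cout, kernel) per convolution, body then head."""
        layers = []
        cin = self.in_channels
        for width in self.block_widths:
            for _ in range(self.convs_per_block):
                layers.append((cin, width, self.kernel_size))
                cin = width
        layers.append((cin, 1, self.final_kernel_size))
        return layers


def receptive_field_extent(config: NetworkConfig) -> int:
    return config.receptive_field_extent


def _conv_same(x: np.ndarray, w: np.ndarray, b: Optional[np.ndarray] = None,
               return_cols: bool = False):
    """Same-padded 2D convolution of a batch.

    x : (N, H, W, Cin);  w : (Cin, k, k, Cout);  returns (N, H, W, Cout).
    """
    cin, k, _, cout = w.shape
    n, h, wd, _ = x.shape
    p = (k - 1) // 2
    if p:
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    else:
        xp = x
    if k == 1:
        cols = x.reshape(n * h * wd, cin)
    else:
        windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # windows: (N, H, W, Cin, k, k) -> rows ordered (Cin, kh, kw)
        cols = windows.reshape(n * h * wd, cin * k * k)
    z = cols @ w.reshape(cin * k * k, cout)
    if b is not None:
        z += b
    z = z.reshape(n, h, wd, cout)
    return (z, cols) if return_cols else z


class _ConvLayer:
    """One convolution with optional ReLU, holding its own Adam-visible state."""

    def __init__(self, cin: int, cout: int, k: int, relu: bool, rng: np.random.Generator,
                 dtype=np.float32):
        bound = 1.0 / np.sqrt(cin * k * k)  # fan-in scaled uniform init
        self.dtype = np.dtype(dtype)
        self.w = rng.uniform(-bound, bound, size=(cin, k, k, cout)).astype(self.dtype)
        self.b = rng.uniform(-bound, bound, size=cout).astype(self.dtype)
        self.relu = relu
        self.k = k
        self._cols = None
        self._mask = None
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            z, cols = _conv_same(x, self.w, self.b, return_cols=True)
            self._cols = cols
        else:
            z = _conv_same(x, self.w, self.b)
        if self.relu:
            if train:
                self._mask = z > 0
                return np.where(self._mask, z, z.dtype.type(0))
            return np.maximum(z, z.dtype.type(0))
        return z

    def backward(self, dz: np.ndarray) -> np.ndarray:
        if self.relu:
            dz = np.where(self._mask, dz, dz.dtype.type(0))
        n, h, wd, cout = dz.shape
        dzf = dz.reshape(n * h * wd, cout)
        cin = self.w.shape[0]
        self.gw = (self._cols.T @ dzf).reshape(self.w.shape)
        self.gb = dzf.sum(axis=0)
        # grad wrt input = same-padded conv with the spatially flipped,
        # channel-transposed kernel
        w_flip = self.w[:, ::-1, ::-1, :].transpose(3, 1, 2, 0)
        dx = _conv_same(dz, np.ascontiguousarray(w_flip))
        self._cols = None
        self._mask = None
        return dx

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size


class Network:
    """The trainable denoising function f_theta.

    Maps an m x n image in [0, 1] to an m x n image in (0, 1).  Output pixel
    (i, j) depends only on input pixels within Chebyshev distance
    (receptive_field_extent - 1) / 2 of (i, j).
    """

    def __init__(self, config: NetworkConfig, seed: int, dtype=np.float32):
        self.config = config
        self.rng_seed = int(seed)
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(self.rng_seed)
        specs = config.layer_channels()
        self.layers = [
            _ConvLayer(cin, cout, k, relu=(idx < len(specs) - 1), rng=rng,
                       dtype=self.dtype)
            for idx, (cin, cout, k) in enumerate(specs)
        ]
        self._sig = None  # cached sigmoid output for backward

    # -- forward / backward -------------------------------------------------

    def _to_batch(self, img: np.ndarray) -> tuple:
        x = np.asarray(img, dtype=self.dtype)
        squeeze = x.ndim
        if x.ndim == 2:
            x = x[None, :, :, None]
        elif x.ndim == 3:  # batch of single-channel images
            x = x[..., None]
        elif x.ndim != 4:
            raise ValueError(f"cannot interpret input of shape {img.shape}")
        if x.shape[-1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} channel(s), got {x.shape[-1]}"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("network input contains NaN or Inf")
        return x, squeeze

    def forward(self, img: np.ndarray, train: bool = False) -> np.ndarray:
        """Apply the network; shape-preserving, output in the open unit interval.

        Accepts (m, n), (N, m, n) or (N, m, n, C) input.  ``train=True``
        caches the activations needed by :meth:`backward`.
        """
        x, ndim_in = self._to_batch(img)
        for layer in self.layers:
            x = layer.forward(x, train)
        sig = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._sig = sig
        out = np.clip(sig, sig.dtype.type(_EPS), sig.dtype.type(1.0 - 1e-7))
        out = out[..., 0]
        if ndim_in == 2:
            out = out[0]
        return out

    def backward(self, dloss_dsig: np.ndarray) -> None:
        """Backpropagate d(loss)/d(sigmoid output); fills each layer's gw/gb."""
        if self._sig is None:
            raise RuntimeError("backward() requires a prior forward(train=True)")
        g = np.asarray(dloss_dsig, dtype=self.dtype)
        if g.ndim == 2:
            g = g[None, :, :, None]
        elif g.ndim == 3:
            g = g[..., None]
        dz = g * self._sig * (self.dtype.type(1) - self._sig)
        for layer in reversed(self.layers):
            dz = layer.backward(dz)
        self._sig = None

    def backward_logits(self, dloss_dz: np.ndarray) -> None:
        """Backpropagate a gradient already expressed w.r.t. the pre-sigmoid
        logits (the numerically stable route for cross-entropy losses)."""
        dz = np.asarray(dloss_dz, dtype=self.dtype)
        if dz.ndim == 2:
            dz = dz[None, :, :, None]
        elif dz.ndim == 3:
            dz = dz[..., None]
        for layer in reversed(self.layers):
            dz = layer.backward(dz)
        self._sig = None

    # -- parameter plumbing -------------------------------------------------

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend([layer.w, layer.b])
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend([layer.gw, layer.gb])
        return out

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: Iterable[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p[...] = s

    def save_weights(self, path: str) -> None:
        np.savez(path, *self.parameters())

    def load_weights(self, path: str) -> None:
        with np.load(path) as archive:
            self.set_state([archive[k] for k in archive.files])


def build_network(config: Optional[NetworkConfig] = None, seed: int = 0,
                  dtype=np.float32) -> Network:
    """Construct a seeded network; identical seeds give identical weights."""
    return Network(config or NetworkConfig(), seed, dtype=dtype)


class AdamOptimizer:
    """Adam with the conventional moment defaults (0.9, 0.999, eps 1e-8)."""

    def __init__(self, params: list, lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = np.float32(lr)
        self.beta1 = np.float32(beta1)
        self.beta2 = np.float32(beta2)
        self.eps = np.float32(eps)
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = np.float32(1.0 - float(b1) ** self.t)
        bc2 = np.float32(1.0 - float(b2) ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m *= b1
            m += (np.float32(1.0) - b1) * g
            v *= b2
            v += (np.float32(1.0) - b2) * (g * g)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
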