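"""Reading, writing and intensity normalization of 2D images.

Images move through the pipeline as :class:`Image2D` planes — one plane per
(frame, channel) combination — so multi-page TIFF stacks and colour images are
denoised plane by plane.  Training happens in normalized [0, 1] space because
the network ends in a sigmoid and the loss is binary cross-entropy; the
min–max affine map is inverted afterwards, so raw intensities are never
clipped on the way in.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import tifffile
from PIL import Image as PILImage

__all__ = [
    "Image2D",
    "NormalizedImage",
    "read_image",
    "write_image",
    "normalize",
    "denormalize",
]

_SUPPORTED_DTYPES = {"uint8": np.uint8, "uint16": np.uint16, "float32": np.float32}


@dataclass
class Image2D:
    """A single rectangular plane of intensities with provenance metadata.

    Parameters
    ----------
    pixels : ndarray of shape (m, n)
        Raw intensities, held as float64 internally.  Never clipped.
    source_dtype : {"uint8", "uint16", "float32"}
        Sample format of the file the plane came from (or should go to).
    channel_index, frame_index : int, optional
        Position of this plane within a colour image / multi-page stack.
    """

    pixels: np.ndarray
    source_dtype: str = "float32"
    channel_index: Optional[int] = None
    frame_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D plane, got shape {self.pixels.shape}")
        m, n = self.pixels.shape
        if m < 2 or n < 2:
            raise ValueError(
                f"image of shape {m}x{n} is too small: chequerboard "
                "downsampling needs at least 2 pixels along each axis"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains NaN or Inf values")
        if self.source_dtype not in _SUPPORTED_DTYPES:
            raise ValueError(
                f"unsupported source_dtype {self.source_dtype!r}; "
                f"expected one of {sorted(_SUPPORTED_DTYPES)}"
            )

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class NormalizedImage:
    """An image affinely mapped to [0, 1], remembering the inverse map.

    ``offset`` is the subtracted minimum and ``scale`` the divided range, so
    ``pixels * scale + offset`` recovers the original intensities.  A constant
    input has no range; it is represented as the constant 0.5 plane with
    ``degenerate=True`` so the trainer can skip it (BCE against a constant
    target is not a trainable problem).
    """

    pixels: np.ndarray
    offset: float
    scale: float
    degenerate: bool = False
    source: Optional[Image2D] = field(default=None, repr=False)

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


def read_image(path: str | os.PathLike) -> list[Image2D]:
    """Read a TIFF or PNG file into one :class:`Image2D` per plane.

    Multi-page files yield one plane per page (``frame_index`` set); colour
    images yield one plane per channel (``channel_index`` set).  Intensities
    are passed through untouched — no clipping, no rescaling.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        data = tifffile.imread(path)
    elif ext == ".png":
        with PILImage.open(path) as im:
            if im.mode == "P":
                im = im.convert("RGB")
            data = np.asarray(im)
    else:
        raise ValueError(f"unsupported file extension {ext!r} (expected TIFF or PNG)")

    dtype_name = data.dtype.name
    if dtype_name == "float64":  # some writers promote; accept as float32 family
        dtype_name = "float32"
    if dtype_name not in _SUPPORTED_DTYPES:
        raise ValueError(
            f"unsupported sample format {data.dtype} in {path!r}; "
            "supported: uint8, uint16, float32"
        )

    planes: list[Image2D] = []
    if data.ndim == 2:
        planes.append(Image2D(data, source_dtype=dtype_name))
    elif data.ndim == 3:
        # Heuristic shared with tifffile/imageio: a trailing axis of length
        # <= 4 is a colour axis, otherwise the leading axis indexes frames.
        if data.shape[-1] <= 4:
            for c in range(data.shape[-1]):
                planes.append(
                    Image2D(data[..., c], source_dtype=dtype_name, channel_index=c)
                )
        else:
            for f in range(data.shape[0]):
                planes.append(
                    Image2D(data[f], source_dtype=dtype_name, frame_index=f)
                )
    elif data.ndim == 4:  # frames x m x n x channels
        for f in range(data.shape[0]):
            for c in range(data.shape[-1]):
                planes.append(
                    Image2D(
                        data[f, ..., c],
                        source_dtype=dtype_name,
                        frame_index=f,
                        channel_index=c,
                    )
                )
    else:
        raise ValueError(f"cannot interpret image of shape {data.shape}")
    return planes


def _cast(pixels: np.ndarray, dtype: str) -> np.ndarray:
    np_dtype = _SUPPORTED_DTYPES[dtype]
    if dtype == "float32":
        return pixels.astype(np.float32)
    info = np.iinfo(np_dtype)
    # round half to even, then clip into the representable range
    rounded = np.rint(pixels)
    return np.clip(rounded, info.min, info.max).astype(np_dtype)


def write_image(
    images: Sequence[Image2D] | Image2D,
    path: str | os.PathLike,
    dtype: Optional[str] = None,
) -> None:
    """Write one or more planes to TIFF (any count) or PNG (single plane).

    Integer targets are rounded half-to-even and clipped to the dtype range;
    float32 output is written verbatim.  ``dtype`` defaults to the first
    plane's ``source_dtype``.
    """
    if isinstance(images, Image2D):
        images = [images]
    if not images:
        raise ValueError("no images to write")
    shapes = {im.shape for im in images}
    if len(shapes) > 1:
        raise ValueError(f"all planes must share one shape, got {sorted(shapes)}")
    dtype = dtype or images[0].source_dtype
    if dtype not in _SUPPORTED_DTYPES:
        raise ValueError(f"unsupported target dtype {dtype!r}")

    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    arrays = [_cast(im.pixels, dtype) for im in images]
    if ext in (".tif", ".tiff"):
        data = arrays[0] if len(arrays) == 1 else np.stack(arrays)
        tifffile.imwrite(path, data, photometric="minisblack")
    elif ext == ".png":
        if dtype == "float32":
            raise ValueError("PNG cannot store float32 samples; use TIFF")
        if len(arrays) == 1:
            PILImage.fromarray(arrays[0]).save(path)
        elif len(arrays) == 3 and dtype == "uint8":
            PILImage.fromarray(np.stack(arrays, axis=-1)).save(path)
        else:
            raise ValueError("PNG output supports one grayscale or three uint8 planes")
    else:
        raise ValueError(f"unsupported output extension {ext!r}")


def normalize(img: Image2D) -> NormalizedImage:
    """Min–max map a plane to [0, 1].

    A constant plane becomes the constant 0.5 plane with the degenerate flag
    set; its stored offset is the constant itself with scale 1, so
    :func:`denormalize` still restores the original exactly.
    """
    px = img.pixels
    lo = float(px.min())
    hi = float(px.max())
    if hi == lo:
        return NormalizedImage(
            pixels=np.full_like(px, 0.5),
            offset=lo - 0.5,
            scale=1.0,
            degenerate=True,
            source=img,
        )
    out = (px - lo) / (hi - lo)
    return NormalizedImage(pixels=out, offset=lo, scale=hi - lo, source=img)


def denormalize(img: NormalizedImage, pixels: Optional[np.ndarray] = None) -> Image2D:
    """Invert :func:`normalize`; optionally map different pixels (for example a
    denoised plane) back through the stored affine transform."""
    px = img.pixels if pixels is None else np.asarray(pixels, dtype=np.float64)
    restored = px * img.scale + img.offset
    if img.source is not None:
        return Image2D(
            restored,
            source_dtype=img.source.source_dtype,
            channel_index=img.source.channel_index,
            frame_index=img.source.frame_index,
        )
    return Image2D(restored)
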