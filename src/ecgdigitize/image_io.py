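"""Image loading, luminance conversion and light denoising."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage

from ecgdigitize.errors import InputError
from ecgdigitize.types import MIN_IMAGE_SIDE, RasterImage

# Rec.601 luminance weights for RGB inputs.
_LUMA = np.array([0.299, 0.587, 0.114])


def load_image(path: str | os.PathLike) -> RasterImage:
    """Load a PNG/JPEG file as a [0, 1] grayscale :class:`RasterImage`.

    Color inputs are reduced to a single luminance channel with the
    Rec.601 weighting; 8-bit values are scaled by 1/255.

    Raises
    ------
    InputError
        If the file is missing/corrupt or smaller than 50x50 pixels.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except (UnidentifiedImageError, OSError) as exc:
        raise InputError(f"cannot decode image {path}: {exc}") from exc

    if arr.ndim == 3:
        arr = arr[..., :3].astype(float) @ _LUMA
    else:
        arr = arr.astype(float)
    arr = arr / 255.0

    if arr.shape[0] < MIN_IMAGE_SIDE or arr.shape[1] < MIN_IMAGE_SIDE:
        raise InputError(
            f"image {path} is {arr.shape[0]}x{arr.shape[1]}; "
            f"minimum is {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}"
        )
    return RasterImage(np.clip(arr, 0.0, 1.0))


def save_image(img: RasterImage, path: str | os.PathLike, jpeg_quality: int | None = None) -> None:
    """Write a RasterImage as 8-bit PNG or JPEG (by extension)."""
    arr = np.clip(np.rint(img.pixels * 255.0), 0, 255).astype(np.uint8)
    pil = Image.fromarray(arr, mode="L")
    if jpeg_quality is not None:
        pil.save(path, quality=jpeg_quality)
    else:
        pil.save(path)


def denoise(img: RasterImage) -> RasterImage:
    """Attenuate isolated specks with a 3x3 median filter (edge replication).

    Dimensions are preserved; extended dark structures such as traces
    survive the filter while single-pixel noise is pulled toward its
    neighborhood.
    """
    out = ndimage.median_filter(img.pixels, size=3, mode="nearest")
    return RasterImage(out)
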