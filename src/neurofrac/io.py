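"""Reading and writing raster images.

Drawings are assumed scanned dark-on-light (ink on paper), so the
default binarization polarity is ``dark``.  PNG, TIFF and BMP are
supported through Pillow; dpi metadata is recorded when the file
carries it.  Saved images follow the scanned-drawing convention:
foreground black on a white background, 8-bit grayscale PNG.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image

from .image import BinaryImage
from .representations import binarize

__all__ = ["SUPPORTED_EXTENSIONS", "load_image", "save_image"]

SUPPORTED_EXTENSIONS = (".png", ".tif", ".tiff", ".bmp")


def load_image(
    path: str,
    threshold: int = 128,
    foreground_polarity: str = "dark",
) -> BinaryImage:
    """Load a PNG/TIFF/BMP file and binarize it.

    Color images are converted to 8-bit grayscale first.  Raises a
    ValueError naming the file if the binarized result has no
    foreground (a blank page cannot be analysed).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in SUPPORTED_EXTENSIONS:
        raise ValueError(f"unsupported image format: {path!r} (expected PNG/TIFF/BMP)")
    with Image.open(path) as im:
        dpi_info = im.info.get("dpi")
        gray = im.convert("L")
        arr = np.asarray(gray, dtype=np.uint8)
    img = binarize(arr, threshold=threshold, foreground_polarity=foreground_polarity)
    if img.is_empty():
        raise ValueError(f"image {path!r} has no foreground after binarization")
    dpi = float(dpi_info[0]) if dpi_info else None
    return img.with_dpi(dpi)


def save_image(img: BinaryImage, path: str) -> None:
    """Write a BinaryImage as an 8-bit PNG/TIFF/BMP, foreground black on white."""
    ext = os.path.splitext(path)[1].lower()
    if ext not in SUPPORTED_EXTENSIONS:
        raise ValueError(f"unsupported image format: {path!r} (expected PNG/TIFF/BMP)")
    arr = np.where(img.mask, 0, 255).astype(np.uint8)
    im = Image.fromarray(arr, mode="L")
    kwargs = {}
    if img.dpi is not None:
        kwargs["dpi"] = (img.dpi, img.dpi)
    im.save(path, **kwargs)
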