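"""Image representations: binary, outline, skeleton.

A neuron drawing is analysed in three presentations, each probing a
different morphological property:

* **binary** — the thresholded drawing itself; its box dimension
  measures how the neuron's projection fills the plane.
* **outline** — the one-pixel-wide border of the foreground; its box
  dimension measures the irregularity of the shape.
* **skeleton** — the medial single-pixel-wide reduction obtained by
  Zhang–Suen thinning; its box dimension measures the complexity of the
  dendritic branching pattern.

Soma removal and other curation (axon/spine deletion, dendrite filling)
are deliberately out of scope: the pipeline expects a pre-cleaned
drawing, as such steps are manual in practice.
"""

from __future__ import annotations

import numpy as np

from .image import BinaryImage, as_binary_image

__all__ = [
    "REPRESENTATIONS",
    "binarize",
    "make_outline",
    "skeletonize",
    "as_representation",
]

#: Closed enumeration of representation tags.
REPRESENTATIONS = ("binary", "outline", "skeleton")


def binarize(
    gray_image: np.ndarray,
    threshold: int = 128,
    foreground_polarity: str = "dark",
) -> BinaryImage:
    """Threshold an 8-bit grayscale image to a BinaryImage.

    With ``foreground_polarity="dark"`` (scanned ink on white paper, the
    default convention) a pixel is foreground iff its value is strictly
    below the threshold; with ``"light"`` iff it is >= threshold.  The
    operation is idempotent: re-thresholding the rendered binary result
    returns the same mask.

    Parameters
    ----------
    gray_image : ndarray
        2D array of intensities in 0..255 (bool arrays are accepted and
        treated as already-binary, True = foreground).
    threshold : int
        Intensity cut in 0..255.
    foreground_polarity : {"dark", "light"}
        Which side of the threshold is foreground.
    """
    arr = np.asarray(gray_image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2D grayscale image")
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in 0..255")
    if arr.dtype == bool:
        return BinaryImage(arr)
    if foreground_polarity == "dark":
        mask = arr < threshold
    elif foreground_polarity == "light":
        mask = arr >= threshold
    else:
        raise ValueError(f"unknown polarity: {foreground_polarity!r}")
    return BinaryImage(mask)


def make_outline(img: BinaryImage | np.ndarray) -> BinaryImage:
    """One-pixel-wide outline of the foreground.

    A foreground pixel belongs to the outline iff at least one of its 8
    neighbours is background; pixels on the image border treat the
    off-image region as background.  The outline is always a subset of
    the input, and a curve that is already one pixel wide is its own
    outline.
    """
    img = as_binary_image(img)
    m = img.mask
    padded = np.pad(m, 1, mode="constant", constant_values=False)
    # interior = pixels whose full 3x3 neighbourhood is foreground
    interior = np.ones_like(m)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            interior &= padded[1 + dr : 1 + dr + m.shape[0], 1 + dc : 1 + dc + m.shape[1]]
    return BinaryImage(m & ~interior, dpi=img.dpi)


def _neighbours(p: np.ndarray) -> list[np.ndarray]:
    """P2..P9 neighbourhood planes (N, NE, E, SE, S, SW, W, NW) of a padded mask."""
    h, w = p.shape[0] - 2, p.shape[1] - 2
    offsets = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
    return [p[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w] for dr, dc in offsets]


def _zhang_suen_pass(mask: np.ndarray, second: bool) -> np.ndarray:
    """One sub-iteration; returns the boolean map of pixels to delete."""
    p = np.pad(mask, 1, mode="constant", constant_values=False).astype(np.uint8)
    n = _neighbours(p)
    p2, p3, p4, p5, p6, p7, p8, p9 = n
    b = p2 + p3 + p4 + p5 + p6 + p7 + p8 + p9
    seq = [p2, p3, p4, p5, p6, p7, p8, p9, p2]
    a = np.zeros_like(b)
    for k in range(8):
        a += (seq[k] == 0) & (seq[k + 1] == 1)
    cond = mask & (b >= 2) & (b <= 6) & (a == 1)
    if not second:
        cond &= (p2 * p4 * p6 == 0) & (p4 * p6 * p8 == 0)
    else:
        cond &= (p2 * p4 * p8 == 0) & (p2 * p6 * p8 == 0)
    return cond


def skeletonize(img: BinaryImage | np.ndarray) -> BinaryImage:
    """Zhang–Suen thinning to a single-pixel-wide skeleton.

    The classical two-sub-iteration parallel algorithm: a foreground
    pixel p with neighbour count B(p) in 2..6 and exactly one 0->1
    transition A(p) around its 8-neighbourhood is deleted when the
    directional products P2*P4*P6 and P4*P6*P8 (first pass) or P2*P4*P8
    and P2*P6*P8 (second pass) vanish.  Passes alternate until a full
    iteration deletes nothing.

    The output is a subset of the input, structures that are already one
    pixel wide are fixed points, and the operation is idempotent.  No
    spur pruning is applied.
    """
    img = as_binary_image(img)
    mask = img.mask.copy()
    while True:
        d1 = _zhang_suen_pass(mask, second=False)
        mask &= ~d1
        d2 = _zhang_suen_pass(mask, second=True)
        mask &= ~d2
        if not (d1.any() or d2.any()):
            break
    return BinaryImage(mask, dpi=img.dpi)


def as_representation(img: BinaryImage | np.ndarray, rep: str) -> BinaryImage:
    """Convert a binary image to one of the three analysis representations."""
    img = as_binary_image(img)
    if rep == "binary":
        return img
    if rep == "outline":
        return make_outline(img)
    if rep == "skeleton":
        return skeletonize(img)
    raise ValueError(f"unknown representation: {rep!r} (expected one of {REPRESENTATIONS})")
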