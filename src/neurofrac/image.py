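"""Binary raster container used throughout the package.

A :class:`BinaryImage` is a rectangular grid of foreground/background
pixels.  Foreground is the ink of a neuron drawing (dendrites, soma);
background is the paper.  All estimators in this package operate on this
one container, so loading, synthesis and representation conversion all
produce it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class BinaryImage:
    """A two-valued raster image.

    Parameters
    ----------
    mask : numpy.ndarray of bool, shape (height, width)
        True where the pixel is foreground.
    dpi : float, optional
        Digitisation resolution tag in dots per inch.  Carried as
        metadata only; no computation depends on physical units.
    """

    mask: np.ndarray
    dpi: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2 or m.size == 0:
            raise ValueError("mask must be a non-empty 2D array")
        if m.dtype != bool:
            m = m.astype(bool)
        object.__setattr__(self, "mask", m)

    # -- basic geometry -------------------------------------------------
    @property
    def height_px(self) -> int:
        return int(self.mask.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.mask.shape[1])

    @property
    def foreground_count(self) -> int:
        """Number of foreground pixels."""
        return int(self.mask.sum())

    def is_empty(self) -> bool:
        return not bool(self.mask.any())

    def bounding_box(self) -> tuple[int, int, int, int]:
        """Tight foreground bounding box as (row0, col0, row1, col1), inclusive.

        Raises
        ------
        ValueError
            If the image has no foreground pixel.
        """
        if self.is_empty():
            raise ValueError("image has no foreground pixels")
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        return int(rows[0]), int(cols[0]), int(rows[-1]), int(cols[-1])

    def cropped(self) -> np.ndarray:
        """Foreground mask cropped to its tight bounding box."""
        r0, c0, r1, c1 = self.bounding_box()
        return self.mask[r0 : r1 + 1, c0 : c1 + 1]

    def foreground_coords(self) -> np.ndarray:
        """(n, 2) array of (row, col) foreground coordinates in raster order."""
        return np.argwhere(self.mask)

    # -- equality helpers ----------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryImage):
            return NotImplemented
        return self.mask.shape == other.mask.shape and bool(
            np.array_equal(self.mask, other.mask)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.mask.shape, self.mask.tobytes()))

    def with_dpi(self, dpi: float | None) -> "BinaryImage":
        return BinaryImage(self.mask, dpi=dpi)


def as_binary_image(obj: "BinaryImage | np.ndarray") -> BinaryImage:
    """Coerce a boolean array or BinaryImage to BinaryImage."""
    if isinstance(obj, BinaryImage):
        return obj
    return BinaryImage(np.asarray(obj))
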