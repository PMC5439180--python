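"""Synthetic binary images with known or controllable fractal properties.

Real Golgi-drawing datasets of neurons are rarely redistributable, so the
package ships generators instead of images: analytic shapes whose box
dimension is known exactly (filled rectangles, digital lines, the
Sierpinski sieve, rasterised disks) and random branching trees that
emulate sparsely branching neurons with a large dendritic domain.  Every
generator is a pure function of its arguments, including the seed, so a
fixture can be regenerated bit-identically anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.draw import line as _draw_line
from scipy import ndimage

from .image import BinaryImage

__all__ = [
    "TreeParams",
    "make_filled_rect",
    "make_line",
    "make_sierpinski",
    "make_disk",
    "make_random_neuron",
    "make_group",
]


@dataclass(frozen=True)
class TreeParams:
    """Parameters of the random branching-tree generator.

    The defaults emulate a sparsely branching neuron with a large
    dendritic field: a handful of primary dendrites leaving a central
    soma point, occasional bifurcations, and thin processes on a canvas
    large enough that the tree never touches the border.

    Attributes
    ----------
    n_primary : int
        Number of primary trunks leaving the soma (>= 1).
    branch_prob : float
        Probability that a segment ends in a bifurcation (0..1).
    segment_len_px : float
        Mean segment length in pixels.
    len_jitter : float
        Relative spread of segment length (0 = fixed length).
    angle_spread_deg : float
        Half-width of the random perturbation applied to the direction
        of a continuing or branching segment.
    max_depth : int
        Maximum number of successive segments along any path.
    thickness_px : int
        Stroke width; 1 draws single-pixel lines, larger values dilate
        the drawing with a square structuring element.
    canvas_px : int
        Side of the square canvas (>= 64).
    seed : int
        RNG seed; identical seed and parameters give a bit-identical
        image.
    """

    n_primary: int = 5
    branch_prob: float = 0.35
    segment_len_px: float = 22.0
    len_jitter: float = 0.3
    angle_spread_deg: float = 35.0
    max_depth: int = 8
    thickness_px: int = 1
    canvas_px: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_primary < 1:
            raise ValueError("n_primary must be >= 1")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must lie in [0, 1]")
        if self.canvas_px < 64:
            raise ValueError("canvas_px must be >= 64")
        if self.thickness_px < 1:
            raise ValueError("thickness_px must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


def make_filled_rect(width_px: int, height_px: int) -> BinaryImage:
    """A completely foreground rectangle.

    The plane-filling control: under the powers-of-two schedule a filled
    side-2^m square quarters its box count each time the box side
    doubles, so its box dimension is exactly 2.
    """
    if width_px < 1 or height_px < 1:
        raise ValueError("rectangle dimensions must be positive")
    return BinaryImage(np.ones((height_px, width_px), dtype=bool))


def make_line(length_px: int, orientation: str = "horizontal") -> BinaryImage:
    """A 1-px-wide digital line of exactly ``length_px`` foreground pixels.

    The one-dimensional control: box counts halve when the box side
    doubles, giving box dimension exactly 1.
    """
    if length_px < 2:
        raise ValueError("length_px must be >= 2")
    if orientation == "horizontal":
        mask = np.ones((1, length_px), dtype=bool)
    elif orientation == "vertical":
        mask = np.ones((length_px, 1), dtype=bool)
    elif orientation == "diagonal":
        mask = np.zeros((length_px, length_px), dtype=bool)
        idx = np.arange(length_px)
        mask[idx, idx] = True
    else:
        raise ValueError(f"unknown orientation: {orientation!r}")
    return BinaryImage(mask)


def make_sierpinski(depth: int) -> BinaryImage:
    """The Sierpinski sieve on a 2^depth canvas.

    Pixel (x, y) is foreground iff ``x & y == 0``; the foreground count
    is 3^depth and, for the origin-aligned grid of side 2^j, exactly
    3^(depth - j) boxes are occupied.  Its box dimension is therefore
    log 3 / log 2 = 1.585 with a perfect log-log fit, which makes it the
    canonical known-dimension validation fixture.
    """
    if not 1 <= depth <= 12:
        raise ValueError("depth must be between 1 and 12")
    side = 2**depth
    x = np.arange(side)
    mask = (x[:, None] & x[None, :]) == 0
    return BinaryImage(mask)


def make_disk(radius_px: int) -> BinaryImage:
    """A rasterised disk with exact 4-fold rotational symmetry.

    Foreground pixels are those whose centre lies within ``radius_px``
    of the canvas centre.  The canvas leaves a margin so rotation never
    clips foreground.
    """
    if radius_px < 2:
        raise ValueError("radius_px must be >= 2")
    margin = max(2, int(math.ceil(0.05 * (2 * radius_px + 1))))
    side = 2 * (radius_px + margin) + 1
    c = side // 2
    yy, xx = np.mgrid[0:side, 0:side]
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2
    return BinaryImage(mask)


def _render_tree(params: TreeParams) -> np.ndarray:
    rng = np.random.default_rng(params.seed)
    n = params.canvas_px
    mask = np.zeros((n, n), dtype=bool)
    margin = max(2, int(math.ceil(0.05 * n))) + (params.thickness_px // 2)
    soma = (n // 2, n // 2)  # (row, col)
    spread = math.radians(params.angle_spread_deg)

    # Depth-first growth with an explicit stack keeps the RNG call order
    # deterministic and avoids recursion limits.
    base = rng.uniform(0.0, 2.0 * math.pi)
    stack: list[tuple[float, float, float, int]] = []
    for i in range(params.n_primary):
        theta = base + 2.0 * math.pi * i / params.n_primary
        stack.append((float(soma[0]), float(soma[1]), theta, 0))

    while stack:
        r, c, theta, depth = stack.pop()
        if depth >= params.max_depth:
            continue
        length = params.segment_len_px * (
            1.0 + params.len_jitter * float(rng.uniform(-1.0, 1.0))
        )
        length = max(2.0, length)
        theta = theta + float(rng.uniform(-spread, spread))
        r2 = r + length * math.sin(theta)
        c2 = c + length * math.cos(theta)
        if not (margin <= r2 < n - margin and margin <= c2 < n - margin):
            continue  # branch stops at the canvas margin
        rr, cc = _draw_line(int(round(r)), int(round(c)), int(round(r2)), int(round(c2)))
        mask[rr, cc] = True
        if float(rng.random()) < params.branch_prob:
            stack.append((r2, c2, theta - spread / 2.0, depth + 1))
            stack.append((r2, c2, theta + spread / 2.0, depth + 1))
        else:
            stack.append((r2, c2, theta, depth + 1))

    if not mask.any():  # degenerate params: keep at least the soma pixel
        mask[soma] = True
    if params.thickness_px > 1:
        struct = np.ones((params.thickness_px, params.thickness_px), dtype=bool)
        mask = ndimage.binary_dilation(mask, structure=struct)
    return mask


def make_random_neuron(params: TreeParams) -> BinaryImage:
    """A random branching tree emulating a sparsely branching neuron.

    Segments grow outward from a central soma point, bifurcating with
    probability ``branch_prob``; the result is a single 8-connected
    component, asymmetric in general, and deterministic given the seed.
    """
    return BinaryImage(_render_tree(params))


def make_group(seed: int, n_images: int, params: TreeParams) -> list[BinaryImage]:
    """A reproducible cohort of independent random trees.

    Per-image seeds are derived as ``seed + index`` so a cohort can be
    extended without reshuffling earlier members.
    """
    if n_images < 2:
        raise ValueError("n_images must be >= 2")
    out = []
    for i in range(n_images):
        p = TreeParams(**{**params.__dict__, "seed": seed + i})
        out.append(make_random_neuron(p))
    return out
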