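"""Independent reference implementations used as test oracles.

Everything here is coded naively and separately from the package —
per-pixel Python loops straight from the definitions — so agreement
with the package is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import numpy as np


def naive_count_boxes(mask: np.ndarray, r: int) -> int:
    """Double-loop box count over the foreground bounding box."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, c0 = rows[0], cols[0]
    r1, c1 = rows[-1], cols[-1]
    count = 0
    for top in range(r0, r1 + 1, r):
        for left in range(c0, c1 + 1, r):
            if mask[top : min(top + r, r1 + 1), left : min(left + r, c1 + 1)].any():
                count += 1
    return count


def _neighbourhood(mask: np.ndarray, y: int, x: int) -> list[int]:
    """P2..P9 in the order N, NE, E, SE, S, SW, W, NW; off-image is 0."""
    h, w = mask.shape

    def at(yy: int, xx: int) -> int:
        if 0 <= yy < h and 0 <= xx < w:
            return int(mask[yy, xx])
        return 0

    return [
        at(y - 1, x), at(y - 1, x + 1), at(y, x + 1), at(y + 1, x + 1),
        at(y + 1, x), at(y + 1, x - 1), at(y, x - 1), at(y - 1, x - 1),
    ]


def naive_zhang_suen(mask: np.ndarray) -> np.ndarray:
    """Per-pixel-loop Zhang-Suen thinning to fixpoint."""
    m = mask.astype(np.uint8).copy()
    changed = True
    while changed:
        changed = False
        for second in (False, True):
            to_delete = []
            for y in range(m.shape[0]):
                for x in range(m.shape[1]):
                    if not m[y, x]:
                        continue
                    p = _neighbourhood(m, y, x)
                    b = sum(p)
                    if not 2 <= b <= 6:
                        continue
                    ring = p + [p[0]]
                    a = sum(
                        1 for k in range(8) if ring[k] == 0 and ring[k + 1] == 1
                    )
                    if a != 1:
                        continue
                    p2, p3, p4, p5, p6, p7, p8, p9 = p
                    if not second:
                        if p2 * p4 * p6 == 0 and p4 * p6 * p8 == 0:
                            to_delete.append((y, x))
                    else:
                        if p2 * p4 * p8 == 0 and p2 * p6 * p8 == 0:
                            to_delete.append((y, x))
            for y, x in to_delete:
                m[y, x] = 0
            if to_delete:
                changed = True
    return m.astype(bool)


def brute_force_diameter(mask: np.ndarray):
    """All-pairs search for the maximal-distance foreground pair.

    Returns the canonical pair under the (first point, then second
    point) lexicographic tie-break, each pair ordered internally.
    """
    coords = [tuple(int(v) for v in rc) for rc in np.argwhere(mask)]
    best_d2 = -1
    best_pair = None
    for i, a in enumerate(coords):
        for b in coords[i:]:
            d2 = (a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2
            pair = (a, b) if a <= b else (b, a)
            if d2 > best_d2 or (d2 == best_d2 and pair < best_pair):
                best_d2 = d2
                best_pair = pair
    return best_pair, best_d2
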