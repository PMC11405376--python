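"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities with the dumbest possible code
(per-box double loops, direct triangle sums) so they stay independent of
the optimized implementation paths they check.
"""

import numpy as np


def naive_box_masses(window: np.ndarray, eps: int, dy: int, dx: int) -> list[int]:
    """Per-cell foreground counts by explicit double loop.

    Mirrors the toroidal-offset convention: the window content is rolled
    by (dy, dx), then tiled from the origin with cells of side ``eps``
    (ragged edge cells padded with background).
    """
    a = np.roll(window.astype(int), (dy, dx), axis=(0, 1))
    h, w = a.shape
    masses = []
    for r0 in range(0, h, eps):
        for c0 in range(0, w, eps):
            total = 0
            for r in range(r0, min(r0 + eps, h)):
                for c in range(c0, min(c0 + eps, w)):
                    total += a[r, c]
            masses.append(total)
    return masses


def naive_box_count(window: np.ndarray, eps: int, dy: int, dx: int) -> int:
    return sum(1 for m in naive_box_masses(window, eps, dy, dx) if m > 0)


def naive_triangle_area_sum(vertices: np.ndarray, faces: np.ndarray) -> float:
    total = 0.0
    for i, j, k in faces:
        a = vertices[j] - vertices[i]
        b = vertices[k] - vertices[i]
        cx = a[1] * b[2] - a[2] * b[1]
        cy = a[2] * b[0] - a[0] * b[2]
        cz = a[0] * b[1] - a[1] * b[0]
        total += 0.5 * (cx * cx + cy * cy + cz * cz) ** 0.5
    return total


def window_of(mask: np.ndarray) -> np.ndarray:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
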