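"""Independent brute-force oracles used only by the test suite.

Each oracle deliberately shares no code with the implementation it checks:
flood fill instead of ndimage labeling, gift wrapping instead of qhull, and
an even-odd ray cast instead of shapely containment.
"""

from __future__ import annotations

import numpy as np

NEIGHBORS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
NEIGHBORS_8 = NEIGHBORS_4 + [(-1, -1), (-1, 1), (1, -1), (1, 1)]


def flood_fill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Label connected components by explicit stack-based flood fill."""
    offsets = NEIGHBORS_4 if connectivity == 1 else NEIGHBORS_8
    labels = np.zeros(mask.shape, dtype=int)
    nr, nc = mask.shape
    current = 0
    for r0 in range(nr):
        for c0 in range(nc):
            if mask[r0, c0] and labels[r0, c0] == 0:
                current += 1
                stack = [(r0, c0)]
                labels[r0, c0] = current
                while stack:
                    r, c = stack.pop()
                    for dr, dc in offsets:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < nr and 0 <= cc < nc and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = current
                            stack.append((rr, cc))
    return labels


def partition(labels: np.ndarray) -> set[frozenset]:
    """Label raster as a set of pixel-index sets (label-renaming invariant)."""
    out: dict[int, set] = {}
    for idx, lab in enumerate(labels.ravel()):
        if lab != 0:
            out.setdefault(int(lab), set()).add(idx)
    return {frozenset(s) for s in out.values()}


def gift_wrap_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull by gift wrapping (Jarvis march); returns hull vertices."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        return pts
    start = min(range(len(pts)), key=lambda i: (pts[i, 1], pts[i, 0]))
    hull = [start]
    while True:
        p = hull[-1]
        q = (p + 1) % len(pts)
        for r in range(len(pts)):
            if r == p:
                continue
            u = pts[q] - pts[p]
            v = pts[r] - pts[p]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (
                cross == 0
                and np.linalg.norm(pts[r] - pts[p]) > np.linalg.norm(pts[q] - pts[p])
            ):
                q = r
        if q == start:
            break
        hull.append(q)
        p = q
    return pts[hull]


def shoelace_area(vertices: np.ndarray) -> float:
    """Polygon area by the shoelace formula."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def hull_area_bruteforce(points: np.ndarray) -> float:
    return shoelace_area(gift_wrap_hull(points))


def raycast_inside(vertices: np.ndarray, r: float, c: float) -> bool:
    """Even-odd point-in-polygon test by horizontal ray casting."""
    v = np.asarray(vertices, dtype=float)
    inside = False
    n = len(v)
    for i in range(n):
        r1, c1 = v[i]
        r2, c2 = v[(i + 1) % n]
        if (r1 > r) != (r2 > r):
            c_cross = c1 + (r - r1) / (r2 - r1) * (c2 - c1)
            if c < c_cross:
                inside = not inside
    return inside


def raycast_mask(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Exhaustive per-pixel-center even-odd rasterization."""
    mask = np.zeros(shape, dtype=bool)
    for i in range(shape[0]):
        for j in range(shape[1]):
            mask[i, j] = raycast_inside(vertices, i + 0.5, j + 0.5)
    return mask
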