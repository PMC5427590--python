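"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (explicit loops, BFS) and shares no
code with the package.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def otsu_bruteforce(image: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive-search Otsu: try every candidate split of a 256-bin
    histogram and return the threshold maximizing between-class variance.

    Computed in exact rational arithmetic so plateau ties (empty bins
    between well-separated modes) are broken deterministically at the
    first maximum, not by float rounding noise.
    """
    from fractions import Fraction

    image = np.asarray(image).ravel()
    counts, edges = np.histogram(image, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    fcounts = [int(c) for c in counts]
    fcenters = [Fraction(float(c)) for c in centers]
    total = sum(fcounts)
    best_var = Fraction(-1)
    best_thr = centers[0]
    for split in range(1, nbins):  # classes [0, split) and [split, nbins)
        w0 = sum(fcounts[:split])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(n * c for n, c in zip(fcounts[:split], fcenters[:split])) / w0
        mu1 = sum(n * c for n, c in zip(fcounts[split:], fcenters[split:])) / w1
        var = Fraction(w0, total) * Fraction(w1, total) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var = var
            best_thr = centers[split - 1]  # last bin of the low class
    return float(best_thr)


def flood_fill_components(binary: np.ndarray) -> list[frozenset[tuple[int, int]]]:
    """8-connected components by BFS flood fill; returns pixel sets."""
    binary = np.asarray(binary).astype(bool)
    seen = np.zeros_like(binary)
    comps = []
    h, w = binary.shape
    for sy in range(h):
        for sx in range(w):
            if not binary[sy, sx] or seen[sy, sx]:
                continue
            comp = set()
            q = deque([(sy, sx)])
            seen[sy, sx] = True
            while q:
                y, x = q.popleft()
                comp.add((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if (
                            0 <= ny < h
                            and 0 <= nx < w
                            and binary[ny, nx]
                            and not seen[ny, nx]
                        ):
                            seen[ny, nx] = True
                            q.append((ny, nx))
            comps.append(frozenset(comp))
    return comps


def point_in_polygon(y: float, x: float, vertices: list[tuple[float, float]]) -> bool:
    """Crossing-number test with explicit on-boundary inclusion."""
    n = len(vertices)
    # boundary check
    for i in range(n):
        y1, x1 = vertices[i]
        y2, x2 = vertices[(i + 1) % n]
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-9:
            if min(x1, x2) - 1e-9 <= x <= max(x1, x2) + 1e-9 and min(
                y1, y2
            ) - 1e-9 <= y <= max(y1, y2) + 1e-9:
                return True
    inside = False
    for i in range(n):
        y1, x1 = vertices[i]
        y2, x2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_int:
                inside = not inside
    return inside


def regional_minima_count(surface: np.ndarray, mask: np.ndarray) -> int:
    """Count regional minima plateaus of ``surface`` inside ``mask`` by BFS.

    A regional minimum is a connected plateau of equal values none of whose
    8-neighbors (inside the mask) is lower.
    """
    surface = np.asarray(surface, dtype=float)
    mask = np.asarray(mask).astype(bool)
    h, w = surface.shape
    seen = np.zeros((h, w), dtype=bool)
    count = 0
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            level = surface[sy, sx]
            plateau = []
            is_min = True
            q = deque([(sy, sx)])
            seen[sy, sx] = True
            while q:
                y, x = q.popleft()
                plateau.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if not (0 <= ny < h and 0 <= nx < w) or not mask[ny, nx]:
                            continue
                        v = surface[ny, nx]
                        if v == level and not seen[ny, nx]:
                            seen[ny, nx] = True
                            q.append((ny, nx))
                        elif v < level:
                            is_min = False
            if is_min:
                count += 1
    return count


def gp_naive(i_b: np.ndarray, i_r: np.ndarray, g: float = 1.0) -> np.ndarray:
    """Elementwise GP by explicit loop."""
    out = np.full(i_b.shape, np.nan)
    for idx in np.ndindex(i_b.shape):
        denom = i_b[idx] + g * i_r[idx]
        if denom > 0:
            out[idx] = (i_b[idx] - g * i_r[idx]) / denom
    return out
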