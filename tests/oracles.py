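"""Independent brute-force oracles used to pin expected values in tests.

Everything here is deliberately naive — explicit loops, O(n²) all-pairs
distances, iterated geodesic dilation — and shares no code with the
implementation it checks.
"""

import numpy as np


def brute_distance_map(binary: np.ndarray) -> np.ndarray:
    """O(n²) all-pairs Euclidean distance to the nearest set pixel."""
    binary = np.asarray(binary, dtype=bool)
    pts = np.argwhere(binary)
    out = np.empty(binary.shape, dtype=float)
    for r in range(binary.shape[0]):
        for c in range(binary.shape[1]):
            d2 = (pts[:, 0] - r) ** 2 + (pts[:, 1] - c) ** 2
            out[r, c] = np.sqrt(d2.min())
    return out


def brute_epsilon(R: np.ndarray, X: np.ndarray, rho: float) -> float:
    """ε via per-pixel distance thresholds instead of dilation."""
    R, X = np.asarray(R, dtype=bool), np.asarray(X, dtype=bool)
    dR = brute_distance_map(R)
    R_tube = dR <= rho
    if X.any():
        dX = brute_distance_map(X)
        X_tube = dX <= rho
    else:
        X_tube = np.zeros_like(X)
    num = np.count_nonzero(X & ~R_tube) + np.count_nonzero(R & ~X_tube)
    return num / np.count_nonzero(R_tube)


def brute_minkowski_disk(X: np.ndarray, rho: float) -> np.ndarray:
    """X ⊕ ρN by explicit offset union over the discrete Euclidean disk."""
    X = np.asarray(X, dtype=bool)
    out = np.zeros_like(X)
    r = int(np.floor(rho))
    h, w = X.shape
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            if dr * dr + dc * dc <= rho * rho:
                src = X[
                    max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)
                ]
                out[
                    max(0, dr) : h + min(0, dr), max(0, dc) : w + min(0, dc)
                ] |= src
    return out


def brute_min_filter(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Erosion by explicit neighbourhood minimum with reflective padding."""
    return _brute_rank(img, footprint, np.min)


def brute_max_filter(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return _brute_rank(img, footprint, np.max)


def _brute_rank(img, footprint, reducer):
    img = np.asarray(img, dtype=float)
    fr, fc = footprint.shape
    pr, pc = fr // 2, fc // 2
    padded = np.pad(img, ((pr, pr), (pc, pc)), mode="reflect")
    out = np.empty_like(img)
    offs = np.argwhere(footprint)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            vals = [padded[r + dr, c + dc] for dr, dc in offs]
            out[r, c] = reducer(vals)
    return out


def brute_reconstruction_by_dilation(marker, mask):
    """Iterated 8-connected geodesic dilation until stability."""
    marker = np.asarray(marker, dtype=float).copy()
    mask = np.asarray(mask, dtype=float)
    cross = np.ones((3, 3), dtype=bool)
    while True:
        dil = brute_max_filter(marker, cross)
        new = np.minimum(dil, mask)
        if np.array_equal(new, marker):
            return new
        marker = new


def brute_regional_maxima(img):
    """Plateau-based regional maxima by flood fill over equal values."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    visited = np.zeros((h, w), dtype=bool)
    out = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            if visited[r, c]:
                continue
            # flood the plateau containing (r, c)
            level = img[r, c]
            stack, plateau, is_max = [(r, c)], [], True
            seen = {(r, c)}
            while stack:
                y, x = stack.pop()
                plateau.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if not (0 <= yy < h and 0 <= xx < w):
                            continue
                        if img[yy, xx] > level:
                            is_max = False
                        elif img[yy, xx] == level and (yy, xx) not in seen:
                            seen.add((yy, xx))
                            stack.append((yy, xx))
            for y, x in plateau:
                visited[y, x] = True
                out[y, x] = is_max
    return out


def brute_nearest_marker_labels(shape, markers):
    """Assign each pixel to its nearest marker point (Euclidean).

    Only meaningful where the nearest marker is unique; callers should
    restrict comparisons to unambiguous pixels.
    """
    pts = np.asarray(markers, dtype=float)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (rows[..., None] - pts[:, 0]) ** 2 + (cols[..., None] - pts[:, 1]) ** 2
    return np.argmin(d2, axis=-1), np.sort(d2, axis=-1)
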