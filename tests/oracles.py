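"""Naive reference implementations used as independent oracles.

Each function computes its result from the mathematical definition
(per-pixel loops, shift-and-compare, brute-force nearest neighbour), not
from the image-processing libraries the package itself uses, so agreement
is evidence and not tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_Y = SOBEL_X.T


def conv2d_replicate(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct O(HW*9) correlation with replicate border padding."""
    img = np.asarray(img, dtype=float)
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    padded = np.pad(img, ((ph, ph), (pw, pw)), mode="edge")
    out = np.zeros_like(img)
    h, w = img.shape
    for y in range(h):
        for x in range(w):
            region = padded[y : y + kh, x : x + kw]
            out[y, x] = float((region * kernel).sum())
    return out


def sobel_magnitude(img: np.ndarray) -> np.ndarray:
    gx = conv2d_replicate(img, SOBEL_X[::-1, ::-1])  # correlation vs convolution
    gy = conv2d_replicate(img, SOBEL_Y[::-1, ::-1])
    return np.hypot(gx, gy)


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    """Offsets of a disk structuring element: |dy|,|dx| with dy^2+dx^2 <= r^2."""
    r = int(radius)
    return [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dy * dy + dx * dx <= r * r
    ]


def _morph(img: np.ndarray, radius: int, reduce_fn) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    out = np.empty_like(img)
    offs = disk_offsets(radius)
    for y in range(h):
        for x in range(w):
            vals = [
                img[y + dy, x + dx]
                for dy, dx in offs
                if 0 <= y + dy < h and 0 <= x + dx < w
            ]
            out[y, x] = reduce_fn(vals)
    return out


def erode_disk(img: np.ndarray, radius: int) -> np.ndarray:
    """Greyscale erosion by a disk; out-of-frame neighbours are ignored."""
    return _morph(img, radius, min)


def dilate_disk(img: np.ndarray, radius: int) -> np.ndarray:
    return _morph(img, radius, max)


def distance_to_mask(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance from every pixel to the nearest True pixel.

    Brute-force nearest-neighbour via a KD-tree over the mask coordinates —
    independent of the sampled-grid EDT algorithm.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    pts = np.argwhere(mask)
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    query = np.column_stack([yy.ravel(), xx.ravel()])
    d, _ = cKDTree(pts).query(query)
    return d.reshape(h, w)


def _dilate_cross(img: np.ndarray) -> np.ndarray:
    """4-connected greyscale dilation (unit cross), used by reconstruction."""
    out = img.copy()
    out[1:, :] = np.maximum(out[1:, :], img[:-1, :])
    out[:-1, :] = np.maximum(out[:-1, :], img[1:, :])
    out[:, 1:] = np.maximum(out[:, 1:], img[:, :-1])
    out[:, :-1] = np.maximum(out[:, :-1], img[:, 1:])
    return out


def reconstruct_by_dilation(seed: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Morphological reconstruction: iterate dilate-and-clip to convergence."""
    cur = np.minimum(np.asarray(seed, float), np.asarray(mask, float))
    while True:
        nxt = np.minimum(_dilate_cross(cur), mask)
        if np.array_equal(nxt, cur):
            return cur
        cur = nxt


def regional_maxima(img: np.ndarray) -> np.ndarray:
    """Plateaus with no strictly greater 4-neighbour, by reconstruction.

    A pixel belongs to a regional maximum iff reconstructing img - eps under
    img fails to recover its value for any small eps; equivalently
    img - reconstruct(img - eps, img) > 0.
    """
    img = np.asarray(img, dtype=float)
    span = float(img.max() - img.min())
    if span == 0:
        return np.ones_like(img, dtype=bool)
    eps = span * 1e-6
    rec = reconstruct_by_dilation(img - eps, img)
    return img - rec > eps / 2


def h_maxima_markers(img: np.ndarray, h: float) -> np.ndarray:
    """Maxima of height >= h: pixels whose value survives to within h of the
    h-suppressed reconstruction (seed img - h, mask img, iterative)."""
    img = np.asarray(img, dtype=float)
    res = 2 * np.finfo(float).resolution * np.abs(img)  # float-roundoff guard
    hmax = reconstruct_by_dilation(img - h - res, img)
    return img - hmax >= h


def weighted_poly_coeffs(
    values: np.ndarray, weights: np.ndarray, degree: int
) -> np.ndarray:
    """Weighted polynomial fit by explicitly formed normal equations."""
    h, w = values.shape
    xs = np.linspace(-1, 1, w) if w > 1 else np.zeros(w)
    ys = np.linspace(-1, 1, h) if h > 1 else np.zeros(h)
    xh, yh = np.meshgrid(xs, ys)
    terms = [(a, d - a) for d in range(degree + 1) for a in range(d + 1)]
    cols = [(xh**a * yh**b).ravel() for a, b in terms]
    A = np.stack(cols, axis=1)
    wv = weights.ravel()
    AtW = A.T * wv
    return np.linalg.solve(AtW @ A, AtW @ values.ravel())
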