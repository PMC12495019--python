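"""Weighted bivariate polynomial surfaces on normalized coordinates.

All polynomial surfaces in the pipeline (the degree-5 in-focus manifold and
the degree-2 local-contrast surface) are expressed in coordinates normalized
to [-1, 1] along each image axis, which keeps the Vandermonde design matrix
well conditioned at any image size.
"""

from __future__ import annotations

import numpy as np


def normalized_coords(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Return (xh, yh) grids mapping pixel indices to [-1, 1].

    Column index 0 maps to -1 and the last column to +1 (and likewise for
    rows).  Degenerate single-pixel axes map to 0.
    """
    h, w = shape
    xs = np.linspace(-1.0, 1.0, w) if w > 1 else np.zeros(w)
    ys = np.linspace(-1.0, 1.0, h) if h > 1 else np.zeros(h)
    return np.meshgrid(xs, ys)


def poly_terms(degree: int) -> list[tuple[int, int]]:
    """Exponent pairs (a, b) with a + b <= degree, in graded order."""
    return [(a, d - a) for d in range(degree + 1) for a in range(d + 1)]


def design_matrix(xh: np.ndarray, yh: np.ndarray, degree: int) -> np.ndarray:
    """Vandermonde-style matrix with one column per term x^a * y^b."""
    xf = np.asarray(xh, dtype=float).ravel()
    yf = np.asarray(yh, dtype=float).ravel()
    cols = [xf**a * yf**b for a, b in poly_terms(degree)]
    return np.stack(cols, axis=1)


def fit_poly_surface(
    values: np.ndarray,
    weights: np.ndarray,
    degree: int,
    rcond_fail: float = 1e-10,
) -> np.ndarray:
    """Weighted least-squares fit of a total-degree-<= ``degree`` polynomial.

    Parameters
    ----------
    values : 2D array of the quantity to fit (e.g. per-pixel argmax slice).
    weights : 2D array of non-negative weights; zero-weight pixels are
        excluded from the fit entirely.
    degree : total degree bound of the bivariate polynomial.

    Returns
    -------
    coeffs : 1D array of coefficients ordered as :func:`poly_terms`.

    Raises
    ------
    ValueError
        If fewer positive-weight pixels than coefficients remain, or the
        weighted design is rank deficient (e.g. all weight on one line).
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape or values.ndim != 2:
        raise ValueError("values and weights must be 2D arrays of equal shape")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    terms = poly_terms(degree)
    mask = weights > 0
    n_ok = int(mask.sum())
    if n_ok < len(terms):
        raise ValueError(
            f"need at least {len(terms)} positive-weight pixels for a degree-"
            f"{degree} fit, got {n_ok}"
        )
    xh, yh = normalized_coords(values.shape)
    A = design_matrix(xh[mask], yh[mask], degree)
    sw = np.sqrt(weights[mask])
    Aw = A * sw[:, None]
    bw = values[mask] * sw
    coeffs, _, rank, _ = np.linalg.lstsq(Aw, bw, rcond=rcond_fail)
    if rank < len(terms):
        raise ValueError(
            "rank-deficient polynomial fit: weighted pixels do not constrain "
            f"all {len(terms)} coefficients (rank {rank}); check the weight mask"
        )
    return coeffs


def eval_poly_surface(
    coeffs: np.ndarray, shape: tuple[int, int], degree: int | None = None
) -> np.ndarray:
    """Evaluate a coefficient vector from :func:`fit_poly_surface` on a grid."""
    coeffs = np.asarray(coeffs, dtype=float)
    if degree is None:
        degree = degree_from_ncoeffs(len(coeffs))
    xh, yh = normalized_coords(shape)
    A = design_matrix(xh, yh, degree)
    return (A @ coeffs).reshape(shape)


def degree_from_ncoeffs(n: int) -> int:
    """Inverse of ``len(poly_terms(d)) == (d+1)(d+2)/2``."""
    d = int(round((np.sqrt(8 * n + 1) - 3) / 2))
    if (d + 1) * (d + 2) // 2 != n:
        raise ValueError(f"{n} is not a triangular coefficient count")
    return d
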