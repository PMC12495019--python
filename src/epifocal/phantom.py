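"""Synthetic phantoms with known ground truth for every pipeline stage.

The generator emulates the geometry of a confluent epithelial monolayer
imaged through a curved focal surface: disk-like nuclei on a
contact-inhibited lattice, cytoplasm tiled as Voronoi regions of the
nuclei, two cytoplasmic protein channels whose per-cell means follow a
bivariate normal with a controllable Pearson correlation, nuclear exclusion
of the proteins, distance-dependent defocus blur around a smooth in-focus
manifold, and Poisson-Gaussian noise.  Separate small factories build
correlated image pairs (for correlation/colocalization tests) and
edge-enrichment images (for wound-edge profiling tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from ._poly import design_matrix, normalized_coords, poly_terms
from .focal import DAPI, PROTEIN_A, PROTEIN_B, ImageStack

# Default intensity model (arbitrary fluorescence units)
DAPI_NUCLEUS = 200.0
DAPI_BACKGROUND = 2.0
PROTEIN_BASE = 100.0
PROTEIN_SD = 20.0
NUCLEAR_RETENTION = 0.25  # protein level in the nucleoplasm relative to cytoplasm
DEFOCUS_SD_PER_SLICE = 0.75  # Gaussian blur sd (px) per slice of defocus
DEFOCUS_SD_MAX = 6.0


@dataclass
class PhantomTruth:
    """Everything needed to verify a rendered phantom downstream."""

    manifold_coeffs: dict[tuple[int, int], float]
    nucleus_centers: np.ndarray  # (n, 2) as (x, y) px
    nucleus_radius: float
    cell_count: int
    channel_corr: float
    edge_enrichment: float
    true_compartment_means: pd.DataFrame
    seed: int
    shape: tuple[int, int] = (128, 128)
    sheet_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not -1.0 <= self.channel_corr <= 1.0:
            raise ValueError("channel_corr must lie in [-1, 1]")
        if self.edge_enrichment < 0:
            raise ValueError("edge_enrichment must be >= 0")


def make_focus_surface(
    coeffs: dict[tuple[int, int], float] | np.ndarray,
    shape: tuple[int, int],
    degree: int = 5,
) -> np.ndarray:
    """Evaluate a bivariate polynomial surface on normalized coordinates.

    ``coeffs`` maps exponent pairs (a, b) to coefficients of x^a * y^b, with
    x, y normalized to [-1, 1] over the frame; an array in graded term order
    is also accepted.  Total degree above 5 is rejected: higher orders
    overfit the sparse nuclear-border evidence the surface is meant to model.
    """
    h, w = shape
    if h < 8 or w < 8:
        raise ValueError("frame must be at least 8x8")
    if isinstance(coeffs, dict):
        for (a, b) in coeffs:
            if a + b > 5:
                raise ValueError(
                    f"term x^{a}*y^{b} has total degree {a + b} > 5; "
                    "focus surfaces are restricted to total degree 5"
                )
        vec = np.zeros(len(poly_terms(degree)))
        order = {t: i for i, t in enumerate(poly_terms(degree))}
        for t, c in coeffs.items():
            vec[order[t]] = c
    else:
        vec = np.asarray(coeffs, dtype=float)
        if len(vec) > len(poly_terms(5)):
            raise ValueError("coefficient vector implies total degree > 5")
    xh, yh = normalized_coords(shape)
    A = design_matrix(xh, yh, degree)
    return (A @ np.pad(vec, (0, A.shape[1] - len(vec)))).reshape(shape)


def random_manifold_coeffs(
    n_slices: int,
    seed: int,
    shape: tuple[int, int] = (128, 128),
    degree: int = 5,
    margin: float = 2.0,
) -> dict[tuple[int, int], float]:
    """Random degree-<=5 surface rescaled to span [margin, n_slices-1-margin]."""
    rng = np.random.default_rng(seed)
    terms = poly_terms(degree)
    # damp high orders so the surface is smooth at frame scale
    raw = {t: rng.normal(0, 1.0 / (1 + t[0] + t[1])) for t in terms}
    surf = make_focus_surface(raw, shape, degree)
    lo, hi = surf.min(), surf.max()
    span = max(hi - lo, 1e-9)
    scale = (n_slices - 1 - 2 * margin) / span
    out = {t: c * scale for t, c in raw.items()}
    out[(0, 0)] = out.get((0, 0), 0.0) + margin - lo * scale
    return out


def place_nuclei(
    n: int,
    shape: tuple[int, int],
    radius: float,
    seed: int | np.random.Generator,
    max_attempts: int = 20000,
) -> np.ndarray:
    """Rejection-sample n nucleus centers with contact-inhibited spacing.

    Centers keep a margin >= radius from the frame edge and a pairwise
    distance >= 2*radius + 2 px so that rendered nuclei never touch.
    """
    h, w = shape
    if n * np.pi * (2 * radius) ** 2 >= h * w:
        raise ValueError(
            f"cannot pack {n} nuclei of radius {radius} into a {h}x{w} frame"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    min_d = 2 * radius + 2
    n_candidates = 16  # best-candidate sampling: evens out coverage like
    centers: list[tuple[float, float]] = []  # contact inhibition does
    attempts = 0
    while len(centers) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"nucleus packing failed: placed {len(centers)}/{n} after "
                f"{max_attempts} attempts"
            )
        attempts += 1
        xs = rng.uniform(radius, w - 1 - radius, n_candidates)
        ys = rng.uniform(radius, h - 1 - radius, n_candidates)
        if not centers:
            centers.append((xs[0], ys[0]))
            continue
        arr = np.asarray(centers)
        d2 = (xs[:, None] - arr[:, 0]) ** 2 + (ys[:, None] - arr[:, 1]) ** 2
        nearest = d2.min(axis=1)
        best = int(np.argmax(nearest))
        if nearest[best] >= min_d**2:
            centers.append((xs[best], ys[best]))
    return np.asarray(centers)


def relax_centers(
    centers: np.ndarray,
    shape: tuple[int, int],
    radius: float,
    iterations: int = 4,
) -> np.ndarray:
    """Lloyd relaxation toward a contact-inhibited lattice.

    Each iteration moves every center to the centroid of its Voronoi region
    (computed on the pixel grid), clipped to the frame margin; a move that
    would violate the pairwise separation 2*radius + 2 is skipped.  This
    evens out the spacing the way contact inhibition does in a confluent
    monolayer, without changing the number of cells.
    """
    h, w = shape
    centers = np.asarray(centers, dtype=float).copy()
    min_d2 = (2 * radius + 2) ** 2
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    for _ in range(iterations):
        _, idx = cKDTree(centers).query(pts)
        for i in range(len(centers)):
            sel = pts[idx == i]
            if len(sel) == 0:
                continue
            cand = sel.mean(axis=0)
            cand[0] = np.clip(cand[0], radius, w - 1 - radius)
            cand[1] = np.clip(cand[1], radius, h - 1 - radius)
            others = np.delete(centers, i, axis=0)
            if np.min(np.sum((others - cand) ** 2, axis=1)) >= min_d2:
                centers[i] = cand
    return centers


def _draw_correlated_means(
    n: int, rho: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell protein means with target Pearson correlation rho.

    Bivariate normal construction; values are floored well above zero so the
    clip is inactive in practice and the sample correlation stays on target.
    """
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    ya = PROTEIN_BASE + PROTEIN_SD * x
    yb = PROTEIN_BASE + PROTEIN_SD * (rho * x + np.sqrt(1 - rho**2) * z)
    return np.maximum(ya, 1.0), np.maximum(yb, 1.0)


def make_phantom_truth(
    n_cells: int = 30,
    shape: tuple[int, int] = (128, 128),
    nucleus_radius: float = 6.0,
    channel_corr: float = 0.7,
    edge_enrichment: float = 1.0,
    n_slices: int = 21,
    seed: int = 0,
    manifold_coeffs: dict[tuple[int, int], float] | None = None,
    sheet_mask: np.ndarray | None = None,
) -> PhantomTruth:
    """Assemble a :class:`PhantomTruth` with drawn centers and means."""
    rng = np.random.default_rng(seed)
    centers = place_nuclei(n_cells, shape, nucleus_radius, rng)
    centers = relax_centers(centers, shape, nucleus_radius)
    ya, yb = _draw_correlated_means(n_cells, channel_corr, rng)
    table = pd.DataFrame(
        {
            "cell_id": np.arange(1, n_cells + 1),
            "a_cyt_mean": ya,
            "a_nuc_mean": ya * NUCLEAR_RETENTION,
            "b_cyt_mean": yb,
            "b_nuc_mean": yb * NUCLEAR_RETENTION,
        }
    )
    if manifold_coeffs is None:
        manifold_coeffs = random_manifold_coeffs(n_slices, seed + 1, shape)
    return PhantomTruth(
        manifold_coeffs=manifold_coeffs,
        nucleus_centers=centers,
        nucleus_radius=nucleus_radius,
        cell_count=n_cells,
        channel_corr=channel_corr,
        edge_enrichment=edge_enrichment,
        true_compartment_means=table,
        seed=seed,
        shape=shape,
        sheet_mask=sheet_mask,
    )


def true_labels(truth: PhantomTruth) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth (cell_id, compartment) label images.

    cell_id is 1..N via nearest-nucleus (Voronoi) assignment clipped to the
    sheet mask, 0 outside; compartment is 0 = none, 1 = nucleus,
    2 = cytoplasm.
    """
    h, w = truth.shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    tree = cKDTree(truth.nucleus_centers)
    dist, idx = tree.query(pts)
    cell_id = (idx + 1).reshape(h, w)
    nucleus = (dist <= truth.nucleus_radius).reshape(h, w)
    if truth.sheet_mask is not None:
        cell_id = np.where(truth.sheet_mask, cell_id, 0)
        nucleus &= truth.sheet_mask
    comp = np.where(cell_id > 0, 2, 0)
    comp[nucleus] = 1
    return cell_id, comp


def render_scene(truth: PhantomTruth) -> dict[str, np.ndarray]:
    """Noise-free, perfectly sharp 2D scene for each channel."""
    cell_id, comp = true_labels(truth)
    t = truth.true_compartment_means
    # lookup tables indexed by cell id (index 0 = background)
    a_cyt = np.concatenate([[0.0], t["a_cyt_mean"].to_numpy()])
    a_nuc = np.concatenate([[0.0], t["a_nuc_mean"].to_numpy()])
    b_cyt = np.concatenate([[0.0], t["b_cyt_mean"].to_numpy()])
    b_nuc = np.concatenate([[0.0], t["b_nuc_mean"].to_numpy()])
    ch_a = np.where(comp == 1, a_nuc[cell_id], np.where(comp == 2, a_cyt[cell_id], 0.0))
    ch_b = np.where(comp == 1, b_nuc[cell_id], np.where(comp == 2, b_cyt[cell_id], 0.0))
    dapi = np.where(comp == 1, DAPI_NUCLEUS, DAPI_BACKGROUND)
    dapi = np.where(comp == 0, 0.0, dapi)
    return {DAPI: dapi, PROTEIN_A: ch_a, PROTEIN_B: ch_b}


def _defocus_slice(
    banks: dict[str, np.ndarray], sds: np.ndarray, sd_map: np.ndarray
) -> dict[str, np.ndarray]:
    """Blend pre-blurred scenes pixelwise according to the local defocus sd."""
    step = sds[1] - sds[0]
    pos = np.clip(sd_map / step, 0.0, len(sds) - 1.000001)
    i0 = pos.astype(int)
    i1 = np.minimum(i0 + 1, len(sds) - 1)
    frac = pos - i0
    rows, cols = np.indices(sd_map.shape)
    out = {}
    for role, bank in banks.items():
        lo = bank[i0, rows, cols]
        hi = bank[i1, rows, cols]
        out[role] = lo * (1.0 - frac) + hi * frac
    return out


#: default noise: shot noise at 1 count per intensity unit (SNR = 10 at the
#: cytoplasmic base intensity of 100) plus 2 units of Gaussian read noise
NOISE_DEFAULT = (2.0, 1.0)


def render_stack(
    truth: PhantomTruth,
    n_slices: int = 21,
    noise: tuple[float, float] = NOISE_DEFAULT,
    pixel_size_um: float = 0.57,
    defocus_per_slice: float = DEFOCUS_SD_PER_SLICE,
) -> tuple[ImageStack, PhantomTruth]:
    """Render a defocused, noisy 3D stack around the truth's focus manifold.

    Each slice k is the sharp scene blurred with a locally varying Gaussian
    of sd = defocus_per_slice * |k - z_f(x, y)| (approximated by blending a
    bank of uniformly pre-blurred scenes), Poisson-resampled at
    ``poisson_scale`` counts per intensity unit when that is positive, then
    perturbed with additive Gaussian noise of sd ``gauss_sd``.
    """
    gauss_sd, poisson_scale = noise
    z_f = make_focus_surface(truth.manifold_coeffs, truth.shape)
    if z_f.min() < 0 or z_f.max() > n_slices - 1:
        raise ValueError("focus manifold leaves the stack's z range")
    scene = render_scene(truth)
    max_sd = min(DEFOCUS_SD_MAX, defocus_per_slice * max(n_slices - 1, 1))
    n_levels = max(int(np.ceil(max_sd / 0.5)) + 1, 2)
    sds = np.linspace(0.0, max_sd, n_levels)
    banks = {
        role: np.stack(
            [img if s == 0 else ndimage.gaussian_filter(img, s) for s in sds]
        )
        for role, img in scene.items()
    }
    rng = np.random.default_rng(truth.seed + 1000)
    slices = {role: [] for role in scene}
    for k in range(n_slices):
        if max_sd == 0:
            blended = {role: img.copy() for role, img in scene.items()}
        else:
            sd_map = np.minimum(defocus_per_slice * np.abs(k - z_f), max_sd)
            blended = _defocus_slice(banks, sds, sd_map)
        for role, img in blended.items():
            out = img
            if poisson_scale > 0:
                out = rng.poisson(np.maximum(out, 0) * poisson_scale) / poisson_scale
            if gauss_sd > 0:
                out = out + rng.normal(0.0, gauss_sd, out.shape)
            slices[role].append(np.maximum(out, 0.0))
    roles = [DAPI, PROTEIN_A, PROTEIN_B]
    voxels = np.stack([np.stack(slices[r]) for r in roles])
    stack = ImageStack(
        voxels=voxels,
        channel_roles={r: i for i, r in enumerate(roles)},
        pixel_size_um=pixel_size_um,
    )
    return stack, truth


def make_correlated_pair(
    rho: float, shape: tuple[int, int], seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pixelwise-correlated image pair with target Pearson correlation rho.

    The generating variables have exactly the requested correlation, so the
    sample coefficient converges to rho at rate 1/sqrt(N pixels).
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(shape)
    z = rng.standard_normal(shape)
    img_a = PROTEIN_BASE + PROTEIN_SD * x
    img_b = PROTEIN_BASE + PROTEIN_SD * (rho * x + np.sqrt(1 - rho**2) * z)
    return img_a, img_b


def make_edge_phantom(
    enrichment: float,
    border_x: int,
    shape: tuple[int, int],
    pixel_size_um: float = 1.0,
    base: float = PROTEIN_BASE,
) -> np.ndarray:
    """Image with a wound-edge enrichment gradient for one channel.

    Zero left of the border column; ``base * enrichment`` in the proximal
    band (0-30 um from the border); a linear ramp over 30-40 um; ``base``
    beyond 40 um.  With enrichment f the proximal/distal interval fraction
    is f / (f + 1) by construction.
    """
    if enrichment < 0:
        raise ValueError("enrichment must be >= 0")
    h, w = shape
    x_um = (np.arange(w) - border_x) * pixel_size_um
    ramp = np.clip((40.0 - x_um) / 10.0, 0.0, 1.0)  # 1 inside 30 um, 0 beyond 40
    profile = base * (1.0 + (enrichment - 1.0) * ramp)
    profile[x_um < 0] = 0.0
    return np.tile(profile, (h, 1))
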