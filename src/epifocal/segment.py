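"""Two-stage marker-controlled watershed segmentation of the in-focus image.

Stage one finds the nucleoplasm of each cell: the DAPI channel is background
subtracted and contrast-flattened, nuclear seed markers come from an
automatically tuned h-maxima transform of its upper half, and a watershed of
the DAPI gradient grows nuclei against an extranuclear marker.  Stage two
partitions the frame into cells: the nuclei become cell seeds, an optional
acellular (void) marker covers cell-free regions detected from the distance
transform, and a watershed of the summed protein-channel gradients — with a
2 px kill zone around nuclei so nuclear borders do not masquerade as cell
borders — draws the cell boundaries.  Compartment means for both protein
channels are then measured per cell.

Structuring-element sizes (sigma = 3 px, radius = 9 px, 2 px erosions and
kill zones) are pixel-unit defaults tuned for ~0.5-0.6 um/px epithelial
imagery and are exposed as parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk, erosion, dilation, h_maxima
from skimage.segmentation import watershed

from ._poly import eval_poly_surface, fit_poly_surface
from .focal import DAPI, PROTEIN_A, PROTEIN_B, InFocusImage, gradient_magnitude

F_NUC_FLOOR_FRACTION = 1e-6  # floor for the contrast surface, x its max


@dataclass
class SegIntermediates:
    """Intermediate images of the segmentation chain, kept for inspection."""

    dapi_smooth: np.ndarray | None = None
    dapi_back: np.ndarray | None = None
    dapi_nuc: np.ndarray | None = None
    f_nuc: np.ndarray | None = None
    dapi_lca: np.ndarray | None = None
    b_nuc: np.ndarray | None = None
    h: float | None = None
    b_exnuc: np.ndarray | None = None
    l1: np.ndarray | None = None
    b_cell: np.ndarray | None = None
    d_avg: float | None = None
    b_void: np.ndarray | None = None
    a2: np.ndarray | None = None
    l2: np.ndarray | None = None


@dataclass
class CompartmentLabels:
    """Combined per-cell segmentation.

    ``cell_id`` is 0 for acellular space and 1..N for cells; ``compartment``
    is 0 = none, 1 = nucleus, 2 = cytoplasm.  Per cell the nucleus and
    cytoplasm partition its support.
    """

    cell_id: np.ndarray
    compartment: np.ndarray
    cell_count: int
    intermediates: SegIntermediates | None = field(default=None, repr=False)


def remove_background(
    dapi_f: np.ndarray, sigma_n: float = 3.0, r_n: int = 9
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Morphological background removal of the in-focus DAPI image.

    A soft background is estimated by greyscale opening-like filtering
    (erosion by a disk of radius r_n, dilation by 2*r_n, Gaussian smoothing)
    which absorbs every object of radius below r_n; subtracting it leaves
    only the nuclei.
    """
    if sigma_n <= 0 or r_n <= 0:
        raise ValueError("sigma_n and r_n must be positive")
    dapi_f = np.asarray(dapi_f, dtype=float)
    if dapi_f.ndim != 2:
        raise ValueError("expected a 2D greyscale image")
    smooth = ndimage.gaussian_filter(dapi_f, sigma_n)
    opened = dilation(erosion(smooth, disk(r_n)), disk(2 * r_n))
    back = ndimage.gaussian_filter(opened, float(r_n))
    nuc = np.maximum(smooth - back, 0.0)
    return smooth, back, nuc


def local_contrast_adjust(
    dapi_nuc: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Self-weighted degree-2 polynomial flattening of nuclear intensity.

    A smooth surface F_nuc is fitted to the nuclear image using the image
    itself as weight (so only nuclei drive the fit), and the image is
    divided by it to equalize nuclear peak heights across the frame.  F_nuc
    is floored at a small positive fraction of its maximum: the ratio is
    only meaningful where nuclear signal exists.
    """
    dapi_nuc = np.asarray(dapi_nuc, dtype=float)
    if not np.any(dapi_nuc > 0):
        raise ValueError("no nuclear signal: cannot adjust contrast")
    coeffs = fit_poly_surface(dapi_nuc, dapi_nuc, degree=2)
    f_nuc = eval_poly_surface(coeffs, dapi_nuc.shape, degree=2)
    floor = F_NUC_FLOOR_FRACTION * f_nuc.max()
    f_nuc = np.maximum(f_nuc, max(floor, np.finfo(float).tiny))
    return f_nuc, dapi_nuc / f_nuc


def nuclear_markers(dapi_lca: np.ndarray) -> tuple[np.ndarray, float]:
    """Nuclear seed mask from an automatically tuned h-maxima transform.

    The image is shifted to its upper 50th percentile (clipped at zero) so
    background plateaus cannot seed; maxima shallower than
    h = 0.1 * prc99.9 are suppressed and the regional maxima of the result
    form the binary marker mask.
    """
    dapi_lca = np.asarray(dapi_lca, dtype=float)
    shifted = np.maximum(dapi_lca - np.percentile(dapi_lca, 50), 0.0)
    h = 0.1 * np.percentile(dapi_lca, 99.9)
    if h <= 0 or not np.any(shifted > 0):
        return np.zeros(dapi_lca.shape, dtype=bool), float(h)
    b_nuc = h_maxima(shifted, h).astype(bool)
    return b_nuc, float(h)


def extranuclear_marker(dapi_lca: np.ndarray) -> np.ndarray:
    """Marker for the space outside nuclei: sub-median pixels, eroded by 2 px."""
    dapi_lca = np.asarray(dapi_lca, dtype=float)
    below = dapi_lca <= np.percentile(dapi_lca, 50)
    return erosion(below, disk(2))


def watershed_nuclei(
    g_dapi_f: np.ndarray, b_nuc: np.ndarray, b_exnuc: np.ndarray
) -> np.ndarray:
    """First watershed: flood the DAPI gradient from nuclear seeds.

    Returns the label image L1 with 1 = extranuclear space and 2..N+1 one
    label per connected nuclear marker.  Every pixel is labeled.
    """
    b_nuc = np.asarray(b_nuc, dtype=bool)
    b_exnuc = np.asarray(b_exnuc, dtype=bool) & ~b_nuc
    if not b_nuc.any():
        warnings.warn("no nuclear markers found: returning a nucleus-free label image")
        return np.ones(g_dapi_f.shape, dtype=np.int32)
    seeds, n = ndimage.label(b_nuc)  # 4-connected components
    markers = np.where(seeds > 0, seeds + 1, 0).astype(np.int32)
    markers[b_exnuc] = 1
    if not b_exnuc.any():
        warnings.warn("empty extranuclear marker: extranuclear label may be absent")
    return watershed(np.asarray(g_dapi_f, dtype=float), markers, connectivity=1)


def estimate_internuclear_distance(
    b_cell: np.ndarray, smoothing_sd_bins: float = 2.0, bin_width: float = 1.0
) -> float:
    """Half the typical spacing between nuclei, from the distance transform.

    The Euclidean distance from every extranuclear pixel to the nearest
    nucleus peaks (in histogram terms) at half the internuclear distance.
    The histogram (1 px bins) is regularized with a Gaussian kernel before
    taking its mode, so a few large cell-free distances cannot shift it.
    """
    b_cell = np.asarray(b_cell, dtype=bool)
    if not b_cell.any():
        raise ValueError("empty nuclear mask")
    if b_cell.all():
        raise ValueError("nuclear mask covers the whole frame")
    if ndimage.label(b_cell)[1] < 2:
        warnings.warn("single nucleus: internuclear distance reflects frame geometry")
    dist = ndimage.distance_transform_edt(~b_cell)
    vals = dist[dist > 0]
    edges = np.arange(0.0, vals.max() + 2 * bin_width, bin_width)
    hist, edges = np.histogram(vals, bins=edges)
    if smoothing_sd_bins > 0:
        hist = ndimage.gaussian_filter1d(hist.astype(float), smoothing_sd_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[np.argmax(hist)])


def void_marker(b_cell: np.ndarray, d_avg: float) -> np.ndarray:
    """Acellular-space marker: opened far-from-any-nucleus region.

    Pixels farther than 2*d_avg from every nucleus, opened with a disk of
    radius d_avg so thin gaps between adjacent cells do not qualify.  Empty
    on confluent sheets.
    """
    b_cell = np.asarray(b_cell, dtype=bool)
    far = ndimage.distance_transform_edt(~b_cell) > 2.0 * d_avg
    r = max(int(round(d_avg)), 1)
    return dilation(erosion(far, disk(r)), disk(r))


def watershed_cells(
    a_f: np.ndarray,
    b_f: np.ndarray,
    l1: np.ndarray,
    b_void: np.ndarray | None = None,
    kill_radius: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Second watershed: separate cells on the protein-channel gradients.

    The relief is the sum of the two protein gradient magnitudes with
    everything within ``kill_radius`` px of nuclear space set to zero, so
    nuclear/cytoplasmic borders cannot be mistaken for cell borders.  Seeds
    are the L1 nuclei (keeping their labels) plus the void marker as
    label 1.  Returns (L2, A2).
    """
    l1 = np.asarray(l1)
    b_cell = l1 > 1
    a2 = gradient_magnitude(a_f) + gradient_magnitude(b_f)
    a2 = np.where(dilation(b_cell, disk(kill_radius)), 0.0, a2)
    markers = np.where(l1 > 1, l1, 0).astype(np.int32)
    if b_void is not None and np.asarray(b_void).any():
        markers[np.asarray(b_void, dtype=bool) & ~b_cell] = 1
    l2 = watershed(a2, markers, connectivity=1)
    return l2, a2


def combine_and_measure(
    l1: np.ndarray,
    l2: np.ndarray,
    a_f: np.ndarray,
    b_f: np.ndarray,
    intermediates: SegIntermediates | None = None,
) -> tuple[CompartmentLabels, pd.DataFrame]:
    """Merge the two watersheds into compartments and measure channel means.

    For cell label l (2..N+1) the nucleus is the L1 region with the same
    label and the cytoplasm the rest of its L2 cell; cells whose nucleus
    vanished (should not occur) are dropped with a warning.  The returned
    table has one row per cell with the mean of each protein channel in each
    compartment.
    """
    l1 = np.asarray(l1)
    l2 = np.asarray(l2)
    a_f = np.asarray(a_f, dtype=float)
    b_f = np.asarray(b_f, dtype=float)
    labels = [int(v) for v in np.unique(l2) if v > 1]
    cell_id = np.zeros(l2.shape, dtype=np.int32)
    comp = np.zeros(l2.shape, dtype=np.int8)
    rows = []
    next_id = 0
    for lab in labels:
        cell = l2 == lab
        nuc = cell & (l1 == lab)
        if not nuc.any():
            warnings.warn(f"cell label {lab} has no nucleus pixels: dropped")
            continue
        next_id += 1
        cyt = cell & ~nuc
        cell_id[cell] = next_id
        comp[nuc] = 1
        comp[cyt] = 2
        ys, xs = np.nonzero(cell)
        rows.append(
            {
                "cell_id": next_id,
                "area_px": int(cell.sum()),
                "nuc_px": int(nuc.sum()),
                "cyt_px": int(cyt.sum()),
                "centroid_x": float(xs.mean()),
                "centroid_y": float(ys.mean()),
                "a_nuc_mean": float(a_f[nuc].mean()),
                "a_cyt_mean": float(a_f[cyt].mean()) if cyt.any() else np.nan,
                "b_nuc_mean": float(b_f[nuc].mean()),
                "b_cyt_mean": float(b_f[cyt].mean()) if cyt.any() else np.nan,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cell_id", "area_px", "nuc_px", "cyt_px", "centroid_x",
            "centroid_y", "a_nuc_mean", "a_cyt_mean", "b_nuc_mean",
            "b_cyt_mean",
        ],
    )
    labels_obj = CompartmentLabels(
        cell_id=cell_id,
        compartment=comp,
        cell_count=next_id,
        intermediates=intermediates,
    )
    return labels_obj, table


def segment_infocus(
    infocus: InFocusImage, sigma_n: float = 3.0, r_n: int = 9
) -> tuple[CompartmentLabels, pd.DataFrame]:
    """Run the full segmentation chain on an in-focus multichannel image."""
    dapi_f = infocus[DAPI]
    a_f = infocus[PROTEIN_A]
    b_f = infocus[PROTEIN_B]
    inter = SegIntermediates()
    inter.dapi_smooth, inter.dapi_back, inter.dapi_nuc = remove_background(
        dapi_f, sigma_n=sigma_n, r_n=r_n
    )
    inter.f_nuc, inter.dapi_lca = local_contrast_adjust(inter.dapi_nuc)
    inter.b_nuc, inter.h = nuclear_markers(inter.dapi_lca)
    inter.b_exnuc = extranuclear_marker(inter.dapi_lca)
    inter.l1 = watershed_nuclei(gradient_magnitude(dapi_f), inter.b_nuc, inter.b_exnuc)
    inter.b_cell = inter.l1 > 1
    if inter.b_cell.any() and not inter.b_cell.all():
        inter.d_avg = estimate_internuclear_distance(inter.b_cell)
        inter.b_void = void_marker(inter.b_cell, inter.d_avg)
    else:
        inter.d_avg = None
        inter.b_void = np.zeros(dapi_f.shape, dtype=bool)
    inter.l2, inter.a2 = watershed_cells(a_f, b_f, inter.l1, inter.b_void)
    return combine_and_measure(inter.l1, inter.l2, a_f, b_f, intermediates=inter)
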