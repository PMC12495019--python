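"""Pixelwise and compartmental colocalization of two protein channels.

Pixelwise: Pearson (linear) and Spearman (monotone) correlation of the two
in-focus channels, with significance assessed by shuffling 8x8-pixel tiles
of one image (preserving local texture while destroying long-range spatial
relation).  Cooccurrence uses the Costes idea — find per-channel thresholds
such that the correlation of the sub-threshold pixels is zero — but the
threshold pair is constrained to a *percentile* pairing (same quantile in
both channels) rather than an orthogonal regression, which tolerates a
nonlinear relation between channels.  Manders coefficients M1/M2 report the
fraction of each channel's total intensity inside the cooccurrence region.

Compartmental: per-cell nucleoplasm fractions nucfr = nuc / (nuc + cyt),
the six pairings of compartment means between and within channels (with
orthogonal regression lines for the scatterplots), and a comparison of
cytoplasmic channel-A levels between cells with high and low channel-B
nuclear fraction (HNF vs LNF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as stats_mod

TILE_DEFAULT = 8
N_PERM_DEFAULT = 200
QUANTILE_STEP_DEFAULT = 0.1
QUANTILE_MAX_DEFAULT = 99.9
HNF_THRESHOLD_DEFAULT = 0.5


@dataclass
class CostesResult:
    th_a: float
    th_b: float
    quantile: float
    m_co: np.ndarray = field(repr=False)
    pcc_costes: float
    pcc_outside: float
    converged: bool


@dataclass
class HnfResult:
    """HNF/LNF group comparison of cytoplasmic channel-A intensity."""

    threshold: float
    n_hnf: int
    n_lnf: int
    performed: bool
    reason: str = ""
    percent_difference: float = float("nan")
    p: float = float("nan")
    comparison: stats_mod.ComparisonResult | None = None


def correlation(x, y, method: str = "pearson") -> float:
    """Pearson or Spearman correlation coefficient of two samples."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with at least 3 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a sample has zero variance")
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def _tile_view(img: np.ndarray, tile: int) -> np.ndarray:
    """Crop to tile multiples and reshape to (n_tiles, tile*tile)."""
    h, w = img.shape
    th, tw = (h // tile) * tile, (w // tile) * tile
    img = img[:th, :tw]
    blocks = img.reshape(th // tile, tile, tw // tile, tile).swapaxes(1, 2)
    return blocks.reshape(-1, tile * tile)


def tile_shuffle_test(
    img_a: np.ndarray,
    img_b: np.ndarray,
    tile: int = TILE_DEFAULT,
    n_perm: int = N_PERM_DEFAULT,
    seed: int | np.random.Generator = 0,
    method: str = "pearson",
) -> tuple[float, float]:
    """Randomization p-value for image correlation by tile shuffling.

    The null distribution comes from correlating tile-permuted copies of
    image A with the fixed image B; the two-sided p-value uses the +1
    convention p = (1 + #{|r_null| >= |r_obs|}) / (n_perm + 1), so it is
    never exactly zero.  Returns (r_observed, p).
    """
    img_a = np.asarray(img_a, dtype=float)
    img_b = np.asarray(img_b, dtype=float)
    if img_a.shape != img_b.shape:
        raise ValueError("images must share a shape")
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19 for usable p-value resolution")
    ta = _tile_view(img_a, tile)
    tb = _tile_view(img_b, tile)
    if ta.shape[0] < 2:
        raise ValueError("tile size leaves fewer than 2 tiles: degenerate null")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    if method == "spearman":
        ta = sps.rankdata(ta.ravel()).reshape(ta.shape)
        tb = sps.rankdata(tb.ravel()).reshape(tb.shape)
    a_flat = ta.ravel()
    b_flat = tb.ravel()
    n = a_flat.size
    sa = a_flat.sum()
    sb = b_flat.sum()
    va = (a_flat**2).sum() - sa**2 / n
    vb = (b_flat**2).sum() - sb**2 / n
    if va == 0 or vb == 0:
        raise ValueError("correlation undefined: an image has zero variance")
    denom = np.sqrt(va * vb)

    def _r(perm: np.ndarray | None) -> float:
        tp = ta if perm is None else ta[perm]
        cross = float(np.einsum("ij,ij->", tp, tb))
        return (cross - sa * sb / n) / denom

    r_obs = _r(None)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(ta.shape[0])
        if abs(_r(perm)) >= abs(r_obs):
            count += 1
    return r_obs, (1 + count) / (n_perm + 1)


def percentile_pairing(
    img_a: np.ndarray, img_b: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Threshold curve pairing equal percentiles of the two images.

    Returns an (len(grid), 2) array of (Th_A(q), Th_B(q)); monotone
    non-decreasing in q by the monotonicity of quantiles.
    """
    grid = np.asarray(grid, dtype=float)
    th_a = np.percentile(np.asarray(img_a, float), grid)
    th_b = np.percentile(np.asarray(img_b, float), grid)
    return np.column_stack([th_a, th_b])


def costes_thresholds(
    img_a: np.ndarray,
    img_b: np.ndarray,
    q_step: float = QUANTILE_STEP_DEFAULT,
    q_max: float = QUANTILE_MAX_DEFAULT,
    tol: float = 0.0,
) -> CostesResult:
    """Percentile-pairing Costes thresholds.

    Walk the percentile curve from high to low quantile; at each step
    compute the Pearson correlation on the *outside* region
    (A <= Th_A or B <= Th_B) and stop at the first step where it drops to
    ``tol`` or below.  If it never does, the thresholds degenerate to the
    curve minimum with a warning (no colocalized population).
    """
    a = np.asarray(img_a, dtype=float).ravel()
    b = np.asarray(img_b, dtype=float).ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Costes thresholds need non-constant images")
    grid = np.arange(q_max, 0.0, -q_step)
    curve = percentile_pairing(a, b, grid)
    last = None
    for q, (th_a, th_b) in zip(grid, curve):
        outside = (a <= th_a) | (b <= th_b)
        n_out = int(outside.sum())
        if n_out < 3:
            continue
        ao, bo = a[outside], b[outside]
        if np.ptp(ao) == 0 or np.ptp(bo) == 0:
            continue
        r_out = float(sps.pearsonr(ao, bo).statistic)
        last = (q, th_a, th_b, r_out)
        if r_out <= tol:
            return _finish_costes(a, b, img_a, q, th_a, th_b, r_out, True)
    warnings.warn(
        "outside-region correlation never reached zero: thresholds set to the "
        "curve minimum (no separable colocalized population)"
    )
    if last is None:
        raise ValueError("percentile curve produced no valid outside region")
    q, th_a, th_b, r_out = last
    return _finish_costes(a, b, img_a, q, th_a, th_b, r_out, False)


def _finish_costes(a, b, img_a, q, th_a, th_b, r_out, converged) -> CostesResult:
    m_co = (a > th_a) & (b > th_b)
    if m_co.sum() >= 3 and np.ptp(a[m_co]) > 0 and np.ptp(b[m_co]) > 0:
        pcc_in = float(sps.pearsonr(a[m_co], b[m_co]).statistic)
    else:
        pcc_in = float("nan")
    return CostesResult(
        th_a=float(th_a),
        th_b=float(th_b),
        quantile=float(q),
        m_co=m_co.reshape(np.asarray(img_a).shape),
        pcc_costes=pcc_in,
        pcc_outside=float(r_out),
        converged=converged,
    )


def manders(
    img_a: np.ndarray, img_b: np.ndarray, m_co: np.ndarray
) -> tuple[float, float]:
    """Manders cooccurrence coefficients.

    M1 (M2) is the fraction of channel A's (B's) total intensity that lies
    inside the cooccurrence mask; both lie in [0, 1] for non-negative
    images.
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    m = np.asarray(m_co, dtype=bool)
    ta, tb = a.sum(), b.sum()
    if ta == 0 or tb == 0:
        raise ValueError("Manders coefficients undefined: zero total intensity")
    return float(a[m].sum() / ta), float(b[m].sum() / tb)


def masked_correlation(
    img_a: np.ndarray, img_b: np.ndarray, mask: np.ndarray
) -> tuple[float, float]:
    """(PCC, SRCC) restricted to the pixels of a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("mask selects fewer than 3 pixels")
    a = np.asarray(img_a, float)[mask]
    b = np.asarray(img_b, float)[mask]
    return correlation(a, b, "pearson"), correlation(a, b, "spearman")


def nuclear_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Append per-cell nucleoplasm fractions for both channels.

    nucfr = nuc / (nuc + cyt) per cell; 0 when the protein is purely
    cytoplasmic, 1 when purely nuclear.
    """
    out = table.copy()
    for ch in ("a", "b"):
        nuc = out[f"{ch}_nuc_mean"].to_numpy(float)
        cyt = out[f"{ch}_cyt_mean"].to_numpy(float)
        tot = nuc + cyt
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, nuc / np.where(tot > 0, tot, 1.0), np.nan)
        out[f"{ch}_nucfr"] = frac
    return out


def orthogonal_regression(x, y) -> tuple[float, float]:
    """First principal axis of the standardized pair, back in data units.

    Standardizing first makes the axis scale-invariant; the de-standardized
    slope is sign(r) * sd(y)/sd(x) with intercept through the means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("orthogonal regression undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = (1.0 if r >= 0 else -1.0) * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    return float(slope), intercept


#: the six compartment-mean pairings examined per cell
COMPARTMENT_PAIRINGS = [
    ("a_nuc_mean", "b_nuc_mean"),
    ("a_cyt_mean", "b_cyt_mean"),
    ("a_nuc_mean", "b_cyt_mean"),
    ("a_cyt_mean", "b_nuc_mean"),
    ("a_nuc_mean", "a_cyt_mean"),
    ("b_nuc_mean", "b_cyt_mean"),
]


def compartment_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Correlations and orthogonal regressions of the compartment pairings.

    One row per pairing (the six compartment pairs plus cytoplasmic A vs the
    nuclear fraction of B) with PCC, SRCC, their analytic two-sided null
    p-values, and the orthogonal-regression slope/intercept.
    """
    if not {"a_nucfr", "b_nucfr"} <= set(table.columns):
        table = nuclear_fractions(table)
    rows = []
    pairings = COMPARTMENT_PAIRINGS + [("a_cyt_mean", "b_nucfr")]
    for cx, cy in pairings:
        sub = table[[cx, cy]].dropna()
        x = sub[cx].to_numpy(float)
        y = sub[cy].to_numpy(float)
        row = {"x": cx, "y": cy, "n": len(sub)}
        if len(sub) >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
            pr = sps.pearsonr(x, y)
            sr = sps.spearmanr(x, y)
            slope, intercept = orthogonal_regression(x, y)
            row.update(
                pcc=float(pr.statistic),
                p_pcc=float(pr.pvalue),
                srcc=float(sr.statistic),
                p_srcc=float(sr.pvalue),
                slope=slope,
                intercept=intercept,
            )
        else:
            row.update(
                pcc=np.nan, p_pcc=np.nan, srcc=np.nan, p_srcc=np.nan,
                slope=np.nan, intercept=np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def hnf_analysis(
    table: pd.DataFrame,
    nucfr_threshold: float = HNF_THRESHOLD_DEFAULT,
    min_cells: int = 5,
) -> HnfResult:
    """Compare cytoplasmic channel A between high- and low-B-nuclear-fraction cells.

    Cells with b_nucfr above the threshold form the HNF group; if at least
    ``min_cells`` qualify, cytoplasmic A is compared between groups with an
    unpaired normality-gated test and the percent difference of the HNF mean
    relative to the LNF mean is reported.  Otherwise the analysis is skipped
    with the reason recorded.
    """
    if not 0 < nucfr_threshold < 1:
        raise ValueError("nucfr_threshold must lie in (0, 1)")
    if "b_nucfr" not in table.columns:
        table = nuclear_fractions(table)
    t = table.dropna(subset=["b_nucfr", "a_cyt_mean"])
    hnf = t["b_nucfr"] > nucfr_threshold
    n_hnf, n_lnf = int(hnf.sum()), int((~hnf).sum())
    if n_hnf < min_cells or n_lnf < min_cells:
        return HnfResult(
            threshold=nucfr_threshold,
            n_hnf=n_hnf,
            n_lnf=n_lnf,
            performed=False,
            reason=f"need >= {min_cells} cells per group (HNF={n_hnf}, LNF={n_lnf})",
        )
    a_hnf = t.loc[hnf, "a_cyt_mean"].to_numpy(float)
    a_lnf = t.loc[~hnf, "a_cyt_mean"].to_numpy(float)
    cmp = stats_mod.compare(a_hnf, a_lnf, design="unpaired")
    pct = 100.0 * (a_hnf.mean() - a_lnf.mean()) / a_lnf.mean()
    return HnfResult(
        threshold=nucfr_threshold,
        n_hnf=n_hnf,
        n_lnf=n_lnf,
        performed=True,
        percent_difference=float(pct),
        p=cmp.p,
        comparison=cmp,
    )


def bivariate_histogram(
    img_a: np.ndarray, img_b: np.ndarray, bins: int = 64
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D intensity histogram as log10(1 + counts), for scatter-style display."""
    h, ex, ey = np.histogram2d(
        np.asarray(img_a, float).ravel(), np.asarray(img_b, float).ravel(), bins=bins
    )
    return np.log10(1.0 + h), ex, ey


def pixel_coloc(
    img_a: np.ndarray,
    img_b: np.ndarray,
    nucleus_mask: np.ndarray | None = None,
    cytoplasm_mask: np.ndarray | None = None,
    tile: int = TILE_DEFAULT,
    n_perm: int = N_PERM_DEFAULT,
    seed: int = 0,
    q_step: float = QUANTILE_STEP_DEFAULT,
) -> dict:
    """Full pixelwise report: correlations, randomization p, Costes, Manders."""
    pcc, p_pcc = tile_shuffle_test(
        img_a, img_b, tile=tile, n_perm=n_perm, seed=seed, method="pearson"
    )
    srcc, p_srcc = tile_shuffle_test(
        img_a, img_b, tile=tile, n_perm=n_perm, seed=seed + 1, method="spearman"
    )
    costes = costes_thresholds(img_a, img_b, q_step=q_step)
    m1, m2 = manders(img_a, img_b, costes.m_co)
    report = {
        "pcc": pcc,
        "p_pcc": p_pcc,
        "srcc": srcc,
        "p_srcc": p_srcc,
        "th_a": costes.th_a,
        "th_b": costes.th_b,
        "costes_quantile": costes.quantile,
        "costes_converged": costes.converged,
        "pcc_costes": costes.pcc_costes,
        "pcc_outside": costes.pcc_outside,
        "m1": m1,
        "m2": m2,
    }
    for name, mask in (("nuc", nucleus_mask), ("cyt", cytoplasm_mask)):
        if mask is not None and np.asarray(mask).sum() >= 3:
            pcc_m, srcc_m = masked_correlation(img_a, img_b, mask)
            report[f"pcc_{name}"] = pcc_m
            report[f"srcc_{name}"] = srcc_m
    return report
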