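"""Wound-edge spatial analysis of protein distribution.

After a capsulotomy, stress-responsive proteins can accumulate in the cells
nearest the cut.  To quantify this, the image is rotated so the cut runs
vertically, columns are averaged into an intensity-vs-distance profile with
distance 0 at the epithelial border, and the profile is resampled into 5 um
bins so samples with different pixel sizes can be pooled.  The interval
fraction IF = <P>_[5,30] / (<P>_[5,30] + <P>_[50,80]) compares a proximal
band against a distal one; 0.5 means equidistribution and values above 0.5
mean proximal accumulation.  The first 5 um (tissue coming gradually into
view) and the 30-50 um transition band are excluded by design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, Polygon

BIN_UM = 5.0
PROXIMAL_UM = (5.0, 30.0)
DISTAL_UM = (50.0, 80.0)
DOMAIN_UM = (0.0, 80.0)


@dataclass
class EdgeProfile:
    """Distance-binned vertical-average intensity profile for one channel."""

    bin_centers_um: np.ndarray
    values: np.ndarray
    channel: str = ""
    border_x: float = 0.0
    rotation_deg: float = 0.0
    bin_um: float = BIN_UM


@dataclass
class IntervalFractions:
    """Proximal/distal interval means and the interval fraction."""

    mean_prox: float
    mean_dist: float
    interval_fraction: float


def _polyline_angle(polyline: np.ndarray) -> float:
    """Rotation (deg) that makes the polyline's principal direction vertical."""
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("polyline must be an (n>=2, 2) array of (x, y)")
    centered = pts - pts.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError("degenerate polyline: all points coincide")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    vx, vy = vt[0]  # principal direction in (x, y)
    # angle of the line from the vertical (y) axis, in (-90, 90]
    ang = np.degrees(np.arctan2(vx, vy))
    if ang > 90:
        ang -= 180
    elif ang <= -90:
        ang += 180
    return float(ang)


def _rotate_points(
    points: np.ndarray, angle_deg: float, center: tuple[float, float]
) -> np.ndarray:
    """Rotate (x, y) points the way ``ndimage.rotate`` moves image content."""
    th = np.radians(angle_deg)
    # ndimage.rotate(angle) moves content counterclockwise in (row, col)
    # display convention, i.e. clockwise in mathematical (x, up-y) terms.
    rot = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
    pts = np.asarray(points, dtype=float) - center
    return pts @ rot.T + center


def align_cut_vertical(
    image: np.ndarray,
    angle_deg: float | None = None,
    border_polyline: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Rotate the frame so the cut/border runs vertically.

    Either an explicit rotation angle or a border polyline (from which the
    angle is the principal direction) must be given.  Returns the bilinearly
    rotated image, the border column (mean rotated polyline x, or the frame
    center when only an angle is given), and the applied angle.
    """
    image = np.asarray(image, dtype=float)
    if angle_deg is None:
        if border_polyline is None:
            raise ValueError("provide angle_deg or border_polyline")
        angle_deg = -_polyline_angle(border_polyline)
    center = ((image.shape[1] - 1) / 2.0, (image.shape[0] - 1) / 2.0)
    if angle_deg == 0.0:
        rotated = image.copy()
    else:
        rotated = ndimage.rotate(
            image, angle_deg, reshape=False, order=1, mode="constant", cval=0.0
        )
    if border_polyline is not None:
        rp = _rotate_points(np.asarray(border_polyline, float), angle_deg, center)
        border_x = float(rp[:, 0].mean())
    else:
        border_x = center[0]
    return rotated, border_x, float(angle_deg)


def vertical_profile(
    image: np.ndarray,
    border_x: float,
    pixel_size_um: float,
    channel: str = "",
    rotation_deg: float = 0.0,
    bin_um: float = BIN_UM,
) -> EdgeProfile:
    """Column-averaged intensity resampled into distance bins from the border.

    Distance of column x is (x - border_x) * pixel_size_um; bins are
    half-open [k*bin, (k+1)*bin) um and each bin averages its member
    columns.  Only non-negative distances (tissue side) are profiled.
    """
    image = np.asarray(image, dtype=float)
    w = image.shape[1]
    if not 0 <= border_x < w:
        raise ValueError(f"border column {border_x} outside frame of width {w}")
    col_means = image.mean(axis=0)
    dist_um = (np.arange(w) - border_x) * pixel_size_um
    keep = dist_um >= 0
    if not keep.any():
        raise ValueError("no columns at non-negative distance from the border")
    d = dist_um[keep]
    v = col_means[keep]
    k = np.floor(d / bin_um).astype(int)
    n_bins = k.max() + 1
    sums = np.bincount(k, weights=v, minlength=n_bins)
    counts = np.bincount(k, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * bin_um
    return EdgeProfile(
        bin_centers_um=centers,
        values=means,
        channel=channel,
        border_x=float(border_x),
        rotation_deg=rotation_deg,
        bin_um=bin_um,
    )


def _interval_mean(profile: EdgeProfile, lo: float, hi: float) -> float:
    """Mean of bins wholly inside [lo, hi) (bin start >= lo, bin end <= hi)."""
    starts = profile.bin_centers_um - profile.bin_um / 2.0
    ends = profile.bin_centers_um + profile.bin_um / 2.0
    sel = (starts >= lo - 1e-9) & (ends <= hi + 1e-9)
    vals = profile.values[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"profile has no bins inside [{lo}, {hi}) um")
    return float(vals.mean())


def interval_fraction(
    profile: EdgeProfile,
    proximal: tuple[float, float] = PROXIMAL_UM,
    distal: tuple[float, float] = DISTAL_UM,
) -> IntervalFractions:
    """Fraction of the proximal-band signal relative to proximal + distal."""
    if profile.bin_centers_um[-1] + profile.bin_um / 2.0 < distal[1] - 1e-9:
        raise ValueError("profile does not cover the distal interval")
    p = _interval_mean(profile, *proximal)
    d = _interval_mean(profile, *distal)
    if p + d == 0:
        warnings.warn("both interval means are zero: interval fraction undefined")
        return IntervalFractions(p, d, float("nan"))
    return IntervalFractions(p, d, p / (p + d))


def normalize_profile(
    profile: EdgeProfile, domain: tuple[float, float] = DOMAIN_UM
) -> EdgeProfile:
    """Divide the profile by its mean over the analysis domain.

    Removes inter-sample intensity variability so profiles from different
    acquisitions can be averaged; the normalized profile has mean 1 over the
    domain, and interval fractions are unchanged.
    """
    m = _interval_mean(profile, *domain)
    if m == 0:
        raise ValueError("profile mean over the domain is zero: cannot normalize")
    return EdgeProfile(
        bin_centers_um=profile.bin_centers_um.copy(),
        values=profile.values / m,
        channel=profile.channel,
        border_x=profile.border_x,
        rotation_deg=profile.rotation_deg,
        bin_um=profile.bin_um,
    )


def aggregate_profiles(profiles: list[EdgeProfile]) -> pd.DataFrame:
    """Per-bin mean, sample SD (n-1) and SEM across samples.

    Bins present in fewer than two samples get NaN SD/SEM (and a single
    sample yields no spread at all).
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    all_centers = sorted({round(float(c), 9) for p in profiles for c in p.bin_centers_um})
    rows = []
    for c in all_centers:
        vals = []
        for p in profiles:
            idx = np.where(np.isclose(p.bin_centers_um, c))[0]
            if idx.size and np.isfinite(p.values[idx[0]]):
                vals.append(float(p.values[idx[0]]))
        n = len(vals)
        mean = float(np.mean(vals)) if n else np.nan
        sd = float(np.std(vals, ddof=1)) if n >= 2 else np.nan
        sem = sd / np.sqrt(n) if n >= 2 else np.nan
        rows.append({"bin_um": c, "n": n, "mean": mean, "sd": sd, "sem": sem})
    return pd.DataFrame(rows)


def destruction_area(
    cut_polyline: np.ndarray, border_polyline: np.ndarray
) -> float:
    """Area (px^2) enclosed between the capsule cut and the cell border.

    The polygon is the cut polyline, the reversed border polyline, and the
    two closing segments; its area comes from the shoelace formula (via
    shapely, which also rejects self-intersecting closures).
    """
    cut = np.asarray(cut_polyline, dtype=float)
    border = np.asarray(border_polyline, dtype=float)
    if cut.ndim != 2 or border.ndim != 2 or len(cut) < 2 or len(border) < 2:
        raise ValueError("polylines must be (n>=2, 2) arrays")
    if LineString(cut).crosses(LineString(border)):
        raise ValueError(
            "cut and border polylines cross: the enclosed region is not a "
            "simple polygon"
        )
    ring = np.vstack([cut, border[::-1]])
    poly = Polygon(ring)
    if poly.area > 0 and not poly.is_valid:
        raise ValueError(
            "cut and border polylines close into a self-intersecting polygon"
        )
    return float(poly.area)
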