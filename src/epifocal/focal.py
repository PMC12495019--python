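"""Focal correction: collapse a curved 3D stack to one in-focus 2D image.

Whole-mount curved epithelia rarely lie flat, so each confocal slice is in
focus only over part of the field.  The in-focus surface is a 2D manifold
z_f(x, y) through the stack.  It is estimated from the DAPI channel: nuclear
borders are the sharpest features, so the slice of maximum Sobel-gradient
magnitude marks the locally best focus.  A total-degree-5 bivariate
polynomial is then fitted to that argmax map by least squares, weighted by
the thresholded gradient magnitude so that featureless pixels do not pull
the fit.  Finally every channel is linearly interpolated along z onto the
fitted surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._poly import eval_poly_surface, fit_poly_surface, poly_terms

#: canonical channel role names
DAPI = "dapi"
PROTEIN_A = "protein_a"
PROTEIN_B = "protein_b"
BRIGHTFIELD = "brightfield"

#: fraction of the 99th percentile below which gradient weights are zeroed
WEIGHT_THRESHOLD_FACTOR = 0.1
WEIGHT_THRESHOLD_PERCENTILE = 99.0


@dataclass
class ImageStack:
    """A multichannel 3D stack I(x, y, z).

    voxels are ordered (channel, z, y, x); ``channel_roles`` maps role names
    (:data:`DAPI`, :data:`PROTEIN_A`, :data:`PROTEIN_B`, optionally
    :data:`BRIGHTFIELD`) to channel indices.
    """

    voxels: np.ndarray
    channel_roles: dict[str, int]
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be (channel, z, y, x)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.z_count < 3:
            raise ValueError("stack must have at least 3 slices")
        n_ch = self.voxels.shape[0]
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < n_ch:
                raise ValueError(f"channel index {idx} for {role!r} out of range")
        if DAPI not in self.channel_roles:
            raise ValueError("stack must declare a DAPI channel")

    @property
    def z_count(self) -> int:
        return self.voxels.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.voxels.shape[2], self.voxels.shape[3]

    def channel(self, role: str) -> np.ndarray:
        """The (z, y, x) sub-stack for one channel role."""
        return self.voxels[self.channel_roles[role]]


@dataclass
class FocusManifold:
    """Fitted in-focus surface and its intermediates."""

    z_m: np.ndarray  # per-pixel argmax slice index
    m_dapi: np.ndarray  # per-pixel max gradient magnitude
    m_dapi_th: np.ndarray  # thresholded weights
    coeffs: np.ndarray  # polynomial coefficients (graded order)
    z_f: np.ndarray  # fitted surface, real-valued, unclamped
    degree: int = 5


@dataclass
class InFocusImage:
    """Per-channel 2D in-focus images keyed by role, plus provenance."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    manifold: FocusManifold | None = field(default=None, repr=False)

    def __getitem__(self, role: str) -> np.ndarray:
        return self.channels[role]


def gradient_magnitude(image: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude of a 2D image.

    Uses the unnormalized 3x3 Sobel kernels with replicate border padding,
    so an interior step edge of height h yields magnitude 4h on the edge
    columns.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("gradient_magnitude expects a 2D image")
    if min(image.shape) < 3:
        raise ValueError("image must be at least 3x3")
    gx = ndimage.sobel(image, axis=1, mode="nearest")
    gy = ndimage.sobel(image, axis=0, mode="nearest")
    return np.hypot(gx, gy)


def max_gradient_projection(dapi_stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel maximum of the slice-wise gradient magnitude and its argmax.

    Ties resolve to the lowest slice index, making the projection
    deterministic.
    """
    dapi_stack = np.asarray(dapi_stack, dtype=float)
    if dapi_stack.ndim != 3 or dapi_stack.shape[0] < 2:
        raise ValueError("need a (z, y, x) stack with at least 2 slices")
    grad = np.stack([gradient_magnitude(s) for s in dapi_stack])
    z_m = np.argmax(grad, axis=0)  # argmax returns the first (lowest) index
    m_dapi = np.take_along_axis(grad, z_m[None], axis=0)[0]
    return m_dapi, z_m


def threshold_weights(m_dapi: np.ndarray) -> np.ndarray:
    """Zero out gradient maxima below 0.1x the 99th percentile.

    Low maxima are dominated by noise rather than nuclear borders and would
    bias the manifold fit.  The percentile uses numpy's linear-interpolation
    convention.
    """
    m_dapi = np.asarray(m_dapi, dtype=float)
    thr = WEIGHT_THRESHOLD_FACTOR * np.percentile(m_dapi, WEIGHT_THRESHOLD_PERCENTILE)
    out = m_dapi.copy()
    out[m_dapi < thr] = 0.0
    return out


def fit_focus_manifold(
    z_m: np.ndarray,
    weights: np.ndarray,
    degree: int = 5,
    m_dapi: np.ndarray | None = None,
) -> FocusManifold:
    """Weighted least-squares polynomial fit of the in-focus surface.

    ``z_f`` is the polynomial evaluated over the full frame; it is *not*
    clamped here — clamping to the valid slice range happens only at
    interpolation time.
    """
    z_m = np.asarray(z_m, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n_terms = len(poly_terms(degree))
    if int((weights > 0).sum()) < n_terms:
        raise ValueError(
            f"need >= {n_terms} positive-weight pixels to fit degree {degree}"
        )
    coeffs = fit_poly_surface(z_m, weights, degree)
    z_f = eval_poly_surface(coeffs, z_m.shape, degree)
    return FocusManifold(
        z_m=z_m,
        m_dapi=m_dapi if m_dapi is not None else weights,
        m_dapi_th=weights,
        coeffs=coeffs,
        z_f=z_f,
        degree=degree,
    )


def interpolate_on_manifold(
    stack: ImageStack,
    manifold: FocusManifold,
    roles: tuple[str, ...] | None = None,
) -> InFocusImage:
    """Linearly interpolate each channel along z onto the fitted surface.

    z_f is clamped to [0, z_count - 1]; each output pixel lies between the
    two slices bracketing z_f there.
    """
    z_f = np.asarray(manifold.z_f, dtype=float)
    if z_f.shape != stack.frame_shape:
        raise ValueError("manifold shape does not match stack frame")
    zc = np.clip(z_f, 0.0, stack.z_count - 1)
    # snap almost-integer surface values so a flat integer manifold
    # reproduces its slice bit-exactly despite least-squares roundoff
    near = np.abs(zc - np.rint(zc)) < 1e-9
    zc = np.where(near, np.rint(zc), zc)
    z0 = np.floor(zc).astype(int)
    z1 = np.minimum(z0 + 1, stack.z_count - 1)
    frac = zc - z0
    if roles is None:
        roles = tuple(r for r in stack.channel_roles if r != BRIGHTFIELD)
    channels: dict[str, np.ndarray] = {}
    rows, cols = np.indices(stack.frame_shape)
    for role in roles:
        sub = np.asarray(stack.channel(role), dtype=float)
        lo = sub[z0, rows, cols]
        hi = sub[z1, rows, cols]
        channels[role] = lo * (1.0 - frac) + hi * frac
    return InFocusImage(
        channels=channels, pixel_size_um=stack.pixel_size_um, manifold=manifold
    )


def correct_stack(stack: ImageStack, degree: int = 5) -> InFocusImage:
    """Full focal correction: gradients -> weights -> fit -> interpolation."""
    m_dapi, z_m = max_gradient_projection(stack.channel(DAPI))
    w = threshold_weights(m_dapi)
    manifold = fit_focus_manifold(z_m, w, degree=degree, m_dapi=m_dapi)
    return interpolate_on_manifold(stack, manifold)
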