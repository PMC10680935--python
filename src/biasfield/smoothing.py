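"""Post-hoc regularizers for predicted bias fields.

Three variants are supported, selected by :class:`SmoothingSpec`:

* ``NS`` — no smoothing (identity);
* ``G``  — separable Gaussian filtering with a truncated, renormalized
  kernel (default 19 voxels wide, sigma 3 voxels, reflective boundary);
* ``B``  — slicewise multilevel least-squares approximation with uniform
  cubic B-splines (default 5 fitting levels), the regularizer family the
  classic iterative correction algorithm uses for its field estimate.

All variants preserve constant fields exactly and are deterministic.
Smoothing operates on the field in linear (exponentiated) space.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.interpolate import BSpline

from .core import EPS
from .volume import Volume

__all__ = [
    "SmoothingSpec",
    "gaussian_smooth",
    "bspline_smooth_slicewise",
    "smooth_field",
    "gaussian_kernel_1d",
    "gaussian_operator_1d",
]


@dataclasses.dataclass
class SmoothingSpec:
    """Which regularizer to apply to a predicted field, and how."""

    mode: str = "G"
    gaussian_sigma: float = 3.0
    gaussian_kernel: int = 19
    spline_order: int = 3
    fitting_levels: int = 5
    slice_axis: int = 2  # axial by convention; the choice is exposed

    def __post_init__(self) -> None:
        if self.mode not in ("NS", "G", "B"):
            raise ValueError(f"unknown smoothing mode {self.mode!r}")
        if self.gaussian_kernel % 2 == 0:
            raise ValueError("gaussian kernel size must be odd")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian sigma must be positive")
        if self.spline_order < 1:
            raise ValueError("spline order must be >= 1")
        if self.fitting_levels < 1:
            raise ValueError("fitting levels must be >= 1")
        if self.slice_axis not in (0, 1, 2):
            raise ValueError("slice axis must be 0, 1 or 2")


# ---------------------------------------------------------------------------
# Gaussian
# ---------------------------------------------------------------------------

def gaussian_kernel_1d(sigma: float, size: int) -> np.ndarray:
    """Truncated Gaussian tap vector of odd length ``size``, sum 1."""
    if size % 2 == 0:
        raise ValueError("kernel size must be odd")
    r = size // 2
    x = np.arange(-r, r + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_smooth(field, sigma: float = 3.0, kernel: int = 19):
    """Separable truncated-Gaussian filtering with reflective boundaries.

    The kernel is renormalized after truncation so constants are exact
    fixed points.
    """
    data = np.asarray(field.data if isinstance(field, Volume) else field,
                      dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("field contains non-finite values")
    taps = gaussian_kernel_1d(sigma, kernel)
    out = data
    for ax in range(out.ndim):
        out = ndimage.correlate1d(out, taps, axis=ax, mode="reflect")
    return field.copy_with(out) if isinstance(field, Volume) else out


def gaussian_operator_1d(n: int, sigma: float = 3.0, kernel: int = 19) -> np.ndarray:
    """The n-by-n matrix of the 1D reflective Gaussian filter.

    Materializing the operator keeps the differentiable smoothing path
    exact: the adjoint needed for backpropagation is simply the
    transpose.  Cheap for the lattice sizes used here (n <= a few
    hundred).
    """
    taps = gaussian_kernel_1d(sigma, kernel)
    return ndimage.correlate1d(np.eye(n), taps, axis=0, mode="reflect")


# ---------------------------------------------------------------------------
# Multilevel B-spline
# ---------------------------------------------------------------------------

def _bspline_design(n: int, order: int, nspans: int) -> np.ndarray:
    """Dense design matrix of a clamped uniform B-spline basis.

    Rows are the ``n`` sample positions mapped to [0, 1]; columns the
    ``nspans + order`` basis functions on an open-uniform knot vector.
    Clamped knots keep the basis a partition of unity on the closed
    interval, so constants live in every level's space and the spaces
    nest as spans double.
    """
    k = order
    interior = np.linspace(0.0, 1.0, nspans + 1)
    t = np.concatenate([np.zeros(k), interior, np.ones(k)])
    x = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
    # design_matrix is right-open at the last knot; nudge the endpoint in
    x = np.clip(x, 0.0, 1.0 - 1e-12)
    return BSpline.design_matrix(x, t, k).toarray()


def _fit_slice_multilevel(sl: np.ndarray, order: int, levels: int) -> np.ndarray:
    """Coarse-to-fine least-squares spline approximation of one 2D slice.

    Level 1 fits a single-span tensor mesh; each later level doubles the
    span count per axis and fits the residual of the accumulated
    reconstruction.
    """
    ny, nx = sl.shape
    recon = np.zeros_like(sl, dtype=float)
    for lev in range(1, levels + 1):
        nspans = 2 ** (lev - 1)
        by = _bspline_design(ny, order, nspans)
        bx = _bspline_design(nx, order, nspans)
        resid = sl - recon
        # separable least squares: min || By C Bx^T - resid ||_F
        c, *_ = np.linalg.lstsq(by, resid, rcond=None)
        c, *_ = np.linalg.lstsq(bx, c.T, rcond=None)
        recon = recon + by @ c.T @ bx.T
    return recon


def bspline_smooth_slicewise(field, order: int = 3, levels: int = 5,
                             axis: int = 2):
    """Replace every 2D slice along ``axis`` by its multilevel spline fit."""
    data = np.asarray(field.data if isinstance(field, Volume) else field,
                      dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("field contains non-finite values")
    in_plane = [data.shape[i] for i in range(3) if i != axis]
    if min(in_plane) < order + 1:
        raise ValueError(
            f"slices of shape {tuple(in_plane)} too small for order-{order} splines"
        )
    moved = np.moveaxis(data, axis, 0)
    out = np.empty_like(moved, dtype=float)
    # cache design matrices across slices (all slices share the lattice)
    for i in range(moved.shape[0]):
        out[i] = _fit_slice_multilevel(moved[i], order, levels)
    out = np.moveaxis(out, 0, axis)
    return field.copy_with(out) if isinstance(field, Volume) else out


def smooth_field(field, spec: SmoothingSpec, clamp_eps: float = EPS):
    """Dispatch on the smoothing mode; ``NS`` is the identity.

    B-spline approximation can undershoot, so its output is clamped at
    ``clamp_eps`` to keep the field usable as a divisor.
    """
    if spec.mode == "NS":
        return field
    if spec.mode == "G":
        return gaussian_smooth(field, spec.gaussian_sigma, spec.gaussian_kernel)
    if spec.mode == "B":
        out = bspline_smooth_slicewise(field, spec.spline_order,
                                       spec.fitting_levels, spec.slice_axis)
        data = out.data if isinstance(out, Volume) else out
        clamped = np.maximum(data, clamp_eps)
        return out.copy_with(clamped) if isinstance(out, Volume) else clamped
    raise ValueError(f"unknown smoothing mode {spec.mode!r}")
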