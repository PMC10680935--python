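"""The multiplicative bias-field model and its masked losses.

An acquired image factorizes voxelwise as a(r) = u(r) b(r), where u is
the unbiased image and b a smooth, strictly positive field.  Taking logs
makes the field additive, log u = log a - log b, so a network can regress
the signed quantity log b.  Training supervises both the field itself and
the image it corrects, with mean-squared errors restricted to a brain
mask of N voxels:

    L_a = (1/N) sum_mask (exp(logb_pred) - b_true)^2
    L_b = (1/N) sum_mask (a / exp(logb_pred) - u_true)^2
    L   = L_a + L_b

Both losses compare in linear intensity space; a pure log-space variant
is exposed via ``space="log"`` for users who prefer it.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .volume import Mask, Volume

__all__ = [
    "EPS",
    "LogBiasField",
    "Sample",
    "apply_bias",
    "correct_with_field",
    "loss_field",
    "loss_corrected",
    "total_loss",
    "loss_gradient",
    "mean_shift_to_reference",
]

#: Clamp for divisions and logs on the normalized [0, 1] intensity scale;
#: far below any tissue intensity, only background zeros ever hit it.
EPS = 1e-6


@dataclasses.dataclass
class LogBiasField:
    """A log bias field on the same lattice as its source volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("log field must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("log field contains non-finite values")

    @property
    def shape(self):
        return tuple(self.data.shape)

    def field(self) -> np.ndarray:
        """The multiplicative field exp(log b), strictly positive."""
        return np.exp(self.data)


@dataclasses.dataclass
class Sample:
    """One training/evaluation unit of the forward model a = u * b."""

    acquired: Volume
    corrected_truth: Volume
    field_truth: Volume
    mask: Mask

    def __post_init__(self) -> None:
        shapes = {self.acquired.shape, self.corrected_truth.shape,
                  self.field_truth.shape, self.mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"Sample components disagree in shape: {shapes}")
        m = self.mask.data
        if m.any() and np.min(self.field_truth.data[m]) <= 0:
            raise ValueError("field_truth must be strictly positive on the mask")


def _as_array(x) -> np.ndarray:
    if isinstance(x, Volume):
        return np.asarray(x.data, dtype=float)
    if isinstance(x, LogBiasField):
        return np.asarray(x.data, dtype=float)
    return np.asarray(x, dtype=float)


def _mask_array(mask) -> np.ndarray:
    m = mask.data if isinstance(mask, Mask) else np.asarray(mask)
    return m.astype(bool)


def _check_shapes(*arrays) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch: {shapes}")


def apply_bias(u, b):
    """Forward model: acquired = corrected * field, voxelwise."""
    ua, ba = _as_array(u), _as_array(b)
    _check_shapes(ua, ba)
    out = ua * ba
    return u.copy_with(out) if isinstance(u, Volume) else out


def correct_with_field(a, field, mask=None, eps: float = EPS):
    """Divide the acquired image by the (smoothed) field.

    The field is defined globally, so voxels outside the mask are divided
    too; ``eps`` clamps the denominator so background zeros cannot blow up.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    aa, fa = _as_array(a), _as_array(field)
    _check_shapes(aa, fa)
    out = aa / np.maximum(fa, eps)
    return a.copy_with(out) if isinstance(a, Volume) else out


def loss_field(logb_pred, b_true, mask, space: str = "linear") -> float:
    """Masked mean squared error between predicted and true bias fields.

    Compares exp(logb_pred) against b_true in linear space by default;
    ``space="log"`` compares logb_pred against log(b_true) instead.
    """
    m = _mask_array(mask)
    if not m.any():
        raise ValueError("empty mask")
    lp, bt = _as_array(logb_pred), _as_array(b_true)
    _check_shapes(lp, bt, m)
    if space == "linear":
        resid = np.exp(lp[m]) - bt[m]
    elif space == "log":
        resid = lp[m] - np.log(np.maximum(bt[m], EPS))
    else:
        raise ValueError(f"unknown loss space {space!r}")
    return float(np.mean(resid ** 2))


def loss_corrected(a, logb_pred, u_true, mask, space: str = "linear") -> float:
    """Masked MSE between the correction a/exp(logb_pred) and u_true."""
    m = _mask_array(mask)
    if not m.any():
        raise ValueError("empty mask")
    aa, lp, ut = _as_array(a), _as_array(logb_pred), _as_array(u_true)
    _check_shapes(aa, lp, ut, m)
    loga = np.log(np.maximum(aa[m], EPS))
    if space == "linear":
        resid = np.exp(loga - lp[m]) - ut[m]
    elif space == "log":
        resid = (loga - lp[m]) - np.log(np.maximum(ut[m], EPS))
    else:
        raise ValueError(f"unknown loss space {space!r}")
    return float(np.mean(resid ** 2))


def total_loss(la: float, lb: float) -> float:
    """Combined objective L = L_a + L_b."""
    if not (np.isfinite(la) and np.isfinite(lb)):
        raise ValueError("loss components must be finite")
    if la < 0 or lb < 0:
        raise ValueError("loss components must be nonnegative")
    return float(la) + float(lb)


def loss_gradient(a, logb_pred, b_true, u_true, mask):
    """(L_a, L_b, dL/dlogb_pred) for the linear-space losses.

    The gradient lattice is zero outside the mask.  Used by the training
    loop to seed backpropagation through the network.
    """
    m = _mask_array(mask)
    n = m.sum()
    if n == 0:
        raise ValueError("empty mask")
    aa, lp = _as_array(a), _as_array(logb_pred)
    bt, ut = _as_array(b_true), _as_array(u_true)
    _check_shapes(aa, lp, bt, ut, m)

    bp = np.exp(lp[m])                      # predicted field
    corr = np.maximum(aa[m], EPS) / bp      # predicted corrected image
    ra = bp - bt[m]
    rb = corr - ut[m]
    la = float(np.mean(ra ** 2))
    lb = float(np.mean(rb ** 2))
    grad = np.zeros_like(lp)
    grad[m] = (2.0 / n) * (ra * bp - rb * corr)
    return la, lb, grad


def mean_shift_to_reference(img, ref, mask, mode: str = "additive"):
    """Shift ``img`` so its masked mean matches ``ref``'s masked mean.

    Compensates for global intensity drift introduced by division-based
    correction.  ``mode="additive"`` (default) adds a constant;
    ``mode="multiplicative"`` rescales by the ratio of masked means.
    """
    m = _mask_array(mask)
    if not m.any():
        raise ValueError("empty mask")
    ia, ra = _as_array(img), _as_array(ref)
    _check_shapes(ia, ra, m)
    mi, mr = float(np.mean(ia[m])), float(np.mean(ra[m]))
    if mode == "additive":
        out = ia + (mr - mi)
    elif mode == "multiplicative":
        if abs(mi) < EPS:
            raise ValueError("masked mean of img is ~0; cannot rescale")
        out = ia * (mr / mi)
    else:
        raise ValueError(f"unknown mean-shift mode {mode!r}")
    return img.copy_with(out) if isinstance(img, Volume) else out
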