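"""Scikit-learn-style estimator wrapping the U-Net field regressor.

:class:`BiasFieldCorrector` owns the whole learnable pipeline: it builds
the network, runs the seeded Adam training loop with best-on-validation
model selection, and exposes ``predict`` (log fields) and ``correct``
(divided, optionally smoothed and mean-matched images).  It follows the
scikit-learn estimator protocol — constructor parameters mirrored as
attributes, ``get_params``/``set_params``, fitted attributes with a
trailing underscore — so it composes with ``clone`` and model-selection
utilities.  The procedural API in :mod:`biasfield.training` is a thin
wrapper over this class.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import core
from .core import EPS, Sample
from .smoothing import SmoothingSpec, gaussian_operator_1d, smooth_field
from .unet import UNet3D, UNetConfig
from .volume import Mask, Volume

__all__ = ["BiasFieldCorrector"]


def _to_samples(X, y=None, masks=None):
    """Accept a list of Sample, or arrays (n,D,H,W) / y=(n,2,D,H,W)."""
    if len(X) and isinstance(X[0], Sample):
        return list(X)
    X = np.asarray(X, dtype=float)
    if X.ndim != 4:
        raise ValueError("X must be (n_samples, D, H, W) or a list of Sample")
    if y is None:
        raise ValueError("y (stacked [field_truth, corrected_truth]) is "
                         "required when X is a plain array")
    y = np.asarray(y, dtype=float)
    if y.shape != (X.shape[0], 2) + X.shape[1:]:
        raise ValueError(f"y must have shape (n, 2, D, H, W), got {y.shape}")
    if masks is None:
        masks = np.ones_like(X, dtype=bool)
    samples = []
    for a, pair, m in zip(X, y, np.asarray(masks)):
        samples.append(Sample(Volume(a), Volume(pair[1]), Volume(pair[0]),
                              Mask(m)))
    return samples


class BiasFieldCorrector(BaseEstimator):
    """Deep bias-field correction as a fit/predict estimator.

    Parameters
    ----------
    levels, base_channels : int
        U-Net depth and width.
    learning_rate : float
        Adam step size (default 1e-4).
    epochs, batch_size : int
        Optimization schedule; gradients are averaged over each batch.
    smoothing : {"NS", "G", "B"}
        Post-hoc regularizer applied to predicted fields in ``correct``.
    smoothing_in_loss : bool
        If True, the Gaussian regularizer sits inside the training loss
        (applied to the exponentiated prediction before both L2 terms);
        modes other than NS/G are rejected there.
    seed : int
        Controls initialization and data ordering; fixing it makes the
        whole training history reproducible.
    """

    def __init__(self, levels: int = 4, base_channels: int = 32,
                 learning_rate: float = 1e-4, epochs: int = 10,
                 batch_size: int = 1, smoothing: str = "G",
                 smoothing_in_loss: bool = False, seed: int = 0,
                 gaussian_sigma: float = 3.0, gaussian_kernel: int = 19,
                 spline_levels: int = 5, verbose: int = 0):
        self.levels = levels
        self.base_channels = base_channels
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.smoothing = smoothing
        self.smoothing_in_loss = smoothing_in_loss
        self.seed = seed
        self.gaussian_sigma = gaussian_sigma
        self.gaussian_kernel = gaussian_kernel
        self.spline_levels = spline_levels
        self.verbose = verbose

    # ------------------------------------------------------------------
    # configuration helpers
    # ------------------------------------------------------------------

    def _unet_config(self) -> UNetConfig:
        return UNetConfig(levels=self.levels, base_channels=self.base_channels,
                          seed=self.seed)

    def smoothing_spec(self, mode: str | None = None) -> SmoothingSpec:
        return SmoothingSpec(mode=mode or self.smoothing,
                             gaussian_sigma=self.gaussian_sigma,
                             gaussian_kernel=self.gaussian_kernel,
                             fitting_levels=self.spline_levels)

    def _smooth_ops(self, shape):
        """Per-axis Gaussian operator matrices for the in-loss path."""
        if not self.smoothing_in_loss:
            return None
        if self.smoothing == "NS":
            return None
        if self.smoothing != "G":
            raise ValueError(
                "smoothing_in_loss supports only NS or G (the B-spline "
                "fit is kept outside the differentiable path)")
        return [gaussian_operator_1d(n, self.gaussian_sigma,
                                     self.gaussian_kernel) for n in shape]

    @staticmethod
    def _apply_ops(x, ops, transpose=False):
        for ax, M in enumerate(ops):
            Mx = M.T if transpose else M
            x = np.moveaxis(np.tensordot(Mx, x, axes=([1], [ax])), 0, ax)
        return x

    # ------------------------------------------------------------------
    # loss
    # ------------------------------------------------------------------

    def _loss_and_grad(self, sample: Sample, logb: np.ndarray, ops,
                       want_grad: bool = True):
        """(la, lb, grad wrt logb) with optional smoothing inside the loss."""
        a = np.asarray(sample.acquired.data, dtype=float)
        bt = np.asarray(sample.field_truth.data, dtype=float)
        ut = np.asarray(sample.corrected_truth.data, dtype=float)
        m = sample.mask.data
        n = m.sum()
        if n == 0:
            raise ValueError("empty mask")
        logb = np.asarray(logb, dtype=float)
        if ops is None:
            la, lb, grad = core.loss_gradient(a, logb, bt, ut, sample.mask)
            return la, lb, (grad if want_grad else None)

        f = np.exp(logb)
        fs = self._apply_ops(f, ops)
        fsm = np.maximum(fs[m], EPS)
        ra = fs[m] - bt[m]
        corr = np.maximum(a[m], EPS) / fsm
        rb = corr - ut[m]
        la = float(np.mean(ra ** 2))
        lb = float(np.mean(rb ** 2))
        if not want_grad:
            return la, lb, None
        gfs = np.zeros_like(fs)
        gfs[m] = (2.0 / n) * (ra - rb * corr / fsm)
        grad = self._apply_ops(gfs, ops, transpose=True) * f
        return la, lb, grad

    # ------------------------------------------------------------------
    # fitting
    # ------------------------------------------------------------------

    def fit(self, X, y=None, masks=None, X_val=None, y_val=None,
            masks_val=None, resume=None):
        """Train on samples, selecting weights by validation total loss.

        ``X`` may be a list of :class:`~biasfield.core.Sample` or an
        array ``(n, D, H, W)`` with ``y = (n, 2, D, H, W)`` stacking
        ``[field_truth, corrected_truth]``.  Without an explicit
        validation set the training set doubles as one.
        ``resume`` takes the state dict produced by
        :meth:`training_state` and continues a checkpointed run.
        """
        from .nn import Adam

        train = _to_samples(X, y, masks)
        if not train:
            raise ValueError("empty training set")
        val = _to_samples(X_val, y_val, masks_val) if X_val is not None else train

        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

        shape = train[0].acquired.shape
        ops = self._smooth_ops(shape)

        if resume is not None:
            net = UNet3D(self._unet_config())
            net.load_state_dict(resume["weights"])
            opt = Adam(net.params(), lr=self.learning_rate)
            opt.load_state_dict(resume["optimizer"])
            rng = np.random.default_rng()
            rng.bit_generator.state = resume["rng_state"]
            history = [dict(r) for r in resume["history"]]
            start_epoch = int(resume["epoch"])
            best_val = float(resume["best_val"])
            best_state = dict(resume["best_weights"])
            best_epoch = int(resume["best_epoch"])
        else:
            net = UNet3D(self._unet_config())
            opt = Adam(net.params(), lr=self.learning_rate)
            rng = np.random.default_rng(self.seed + 1)
            history, start_epoch = [], 0
            best_val, best_state, best_epoch = np.inf, None, -1

        bs = max(1, int(self.batch_size))
        for epoch in range(start_epoch, self.epochs):
            order = rng.permutation(len(train))
            tr_la = tr_lb = 0.0
            for b0 in range(0, len(order), bs):
                batch = order[b0:b0 + bs]
                opt.zero_grad()
                for idx in batch:
                    s = train[idx]
                    logb = net.forward(s.acquired.data)
                    la, lb, grad = self._loss_and_grad(s, logb, ops)
                    if not (np.isfinite(la) and np.isfinite(lb)):
                        raise FloatingPointError(
                            f"non-finite loss at epoch {epoch}, sample {idx}: "
                            f"la={la}, lb={lb}")
                    net.backward(grad / len(batch))
                    tr_la += la
                    tr_lb += lb
                opt.step()
            tr_la /= len(train)
            tr_lb /= len(train)

            va_la = va_lb = 0.0
            for s in val:
                logb = net.forward(s.acquired.data)
                la, lb, _ = self._loss_and_grad(s, logb, ops, want_grad=False)
                va_la += la
                va_lb += lb
            va_la /= len(val)
            va_lb /= len(val)
            row = {"epoch": epoch, "train_loss": tr_la + tr_lb,
                   "train_la": tr_la, "train_lb": tr_lb,
                   "val_loss": va_la + va_lb, "val_la": va_la,
                   "val_lb": va_lb}
            history.append(row)
            if self.verbose:
                print(f"epoch {epoch}: train {row['train_loss']:.6f} "
                      f"val {row['val_loss']:.6f}")
            if row["val_loss"] < best_val:
                best_val = row["val_loss"]
                best_state = net.state_dict()
                best_epoch = epoch

        self._last_state = {
            "weights": net.state_dict(),
            "optimizer": opt.state_dict(),
            "rng_state": rng.bit_generator.state,
            "epoch": self.epochs,
            "best_val": best_val,
            "best_weights": best_state,
            "best_epoch": best_epoch,
            "history": [dict(r) for r in history],
        }
        net.load_state_dict(best_state)
        self.net_ = net
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = best_val
        return self

    def training_state(self) -> dict:
        """Resumable end-of-run state (current weights, Adam moments, RNG)."""
        if not hasattr(self, "_last_state"):
            raise RuntimeError("estimator has not been fitted")
        return self._last_state

    # ------------------------------------------------------------------
    # inference
    # ------------------------------------------------------------------

    def _require_fitted(self):
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator has not been fitted; call fit() "
                               "or load a checkpoint")

    def predict(self, X) -> np.ndarray:
        """Log bias field(s) for normalized volume(s).

        Accepts one 3D array/Volume or a stack ``(n, D, H, W)``.
        """
        self._require_fitted()
        if isinstance(X, Volume):
            X = X.data
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            return np.asarray(self.net_.forward(X), dtype=float)
        return np.stack([np.asarray(self.net_.forward(x), dtype=float)
                         for x in X])

    def predict_field(self, X, smoothing: str | None = None) -> np.ndarray:
        """Exponentiated, optionally smoothed multiplicative field(s)."""
        logb = self.predict(X)
        spec = self.smoothing_spec(smoothing)
        if logb.ndim == 3:
            return np.asarray(smooth_field(np.exp(logb), spec))
        return np.stack([np.asarray(smooth_field(np.exp(l), spec))
                         for l in logb])

    def correct(self, X, mask=None, smoothing: str | None = None,
                match_mean: bool = False):
        """Divide input volume(s) by the predicted smoothed field."""
        field = self.predict_field(X, smoothing)
        data = X.data if isinstance(X, Volume) else np.asarray(X, dtype=float)
        out = core.correct_with_field(data, field)
        if match_mean:
            if mask is None:
                raise ValueError("match_mean requires a mask")
            m = mask if isinstance(mask, Mask) else Mask(np.asarray(mask))
            out = core.mean_shift_to_reference(out, data, m)
        if isinstance(X, Volume):
            return X.copy_with(out)
        return out

    transform = correct

    def score(self, X, y=None, masks=None) -> float:
        """Negative mean total loss over samples (higher is better)."""
        self._require_fitted()
        samples = _to_samples(X, y, masks)
        ops = self._smooth_ops(samples[0].acquired.shape)
        tot = 0.0
        for s in samples:
            logb = self.net_.forward(s.acquired.data)
            la, lb, _ = self._loss_and_grad(s, logb, ops, want_grad=False)
            tot += la + lb
        return -tot / len(samples)
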