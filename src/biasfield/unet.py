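"""The 3D U-Net field estimator.

Maps a normalized T1w volume to a same-shape log bias field: an encoder
of ``levels`` resolution stages (two 3x3x3 conv + instance norm + leaky
ReLU per stage, 2x max pooling between), a mirrored decoder with
stride-2 transpose convolutions and channel-concatenating skip
connections, and a final 1x1x1 linear projection.  No output
nonlinearity — a log field is signed.

Depth and width are configurable; the deliberately small desk-scale
variants (levels=2-3, base_channels=4-8 on 32-48 voxel cubes) are
first-class citizens, not test shims.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import (Conv1x1, Conv3d, ConvTranspose3d, InstanceNorm3d, LeakyReLU,
                 MaxPool3d)

__all__ = ["UNetConfig", "UNet3D", "build_unet", "predict_log_field"]


@dataclasses.dataclass
class UNetConfig:
    """Architecture hyperparameters; spatial sides of any input must be
    divisible by ``2**(levels - 1)``."""

    levels: int = 4
    base_channels: int = 32
    in_channels: int = 1
    out_channels: int = 1
    activation_slope: float = 0.01
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")

    @property
    def divisor(self) -> int:
        return 2 ** (self.levels - 1)


class _ConvBlock:
    """Two (conv -> instance norm -> leaky ReLU) stages."""

    def __init__(self, cin, cout, rng, slope, dtype, name):
        self.layers = []
        for j, ci in enumerate((cin, cout)):
            self.layers += [
                Conv3d(ci, cout, rng, slope, dtype=dtype, name=f"{name}.conv{j}"),
                InstanceNorm3d(cout, dtype=dtype, name=f"{name}.norm{j}"),
                LeakyReLU(slope),
            ]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class UNet3D:
    """Encoder-decoder network predicting a log bias field."""

    def __init__(self, config: UNetConfig):
        self.config = config
        dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(config.seed)
        L, B, s = config.levels, config.base_channels, config.activation_slope

        self.enc = []
        cin = config.in_channels
        for i in range(L):
            cout = B * 2 ** i
            self.enc.append(_ConvBlock(cin, cout, rng, s, dtype, f"enc{i}"))
            cin = cout
        self.pools = [MaxPool3d() for _ in range(L - 1)]

        self.ups, self.dec = [], []
        for i in range(L - 2, -1, -1):
            chi, clo = B * 2 ** (i + 1), B * 2 ** i
            self.ups.append(ConvTranspose3d(chi, clo, rng, s, dtype=dtype,
                                            name=f"up{i}"))
            self.dec.append(_ConvBlock(2 * clo, clo, rng, s, dtype,
                                       f"dec{i}"))
        # zero-initialized pointwise head: the untrained network predicts
        # log b = 0 (identity field), a sensible prior for field regression
        self.head = Conv1x1(B, config.out_channels, rng, s, zero_init=True,
                            dtype=dtype, name="head")
        self._skip_channels = [B * 2 ** i for i in range(L - 1)]

    # -- parameter plumbing -------------------------------------------------

    def params(self):
        out = []
        for blk in self.enc:
            out += blk.params()
        for up, blk in zip(self.ups, self.dec):
            out += up.params() + blk.params()
        out += self.head.params()
        return out

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def state_dict(self) -> dict:
        return {p.name: p.value.copy() for p in self.params()}

    def load_state_dict(self, state: dict) -> None:
        for p in self.params():
            if p.name not in state:
                raise KeyError(f"checkpoint missing parameter {p.name!r}")
            val = np.asarray(state[p.name])
            if val.shape != p.value.shape:
                raise ValueError(
                    f"parameter {p.name!r}: checkpoint shape {val.shape} "
                    f"!= model shape {p.value.shape}")
            p.value = val.astype(p.value.dtype).copy()
            p.grad = np.zeros_like(p.value)

    # -- forward / backward -------------------------------------------------

    def _check_shape(self, shape) -> None:
        d = self.config.divisor
        if any(s % d for s in shape):
            raise ValueError(
                f"input sides {tuple(shape)} must be divisible by {d} "
                f"for a {self.config.levels}-level network")

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (D, H, W) or (C, D, H, W) -> log field of the same spatial shape."""
        if x.ndim == 3:
            x = x[None]
        if not np.all(np.isfinite(x)):
            raise ValueError("network input contains non-finite values")
        self._check_shape(x.shape[1:])
        x = x.astype(self.config.dtype, copy=False)

        skips = []
        for i, blk in enumerate(self.enc):
            x = blk.forward(x)
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x)
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([skip, x], axis=0)
            x = blk.forward(x)
        y = self.head.forward(x)
        return y[0] if self.config.out_channels == 1 else y

    def backward(self, gy: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/d(log field)."""
        if gy.ndim == 3:
            gy = gy[None]
        gy = gy.astype(self.config.dtype, copy=False)
        g = self.head.backward(gy)
        # decoder stages were built coarse-to-fine; reverse traversal walks
        # fine-to-coarse, so skip_grads[i] ends up belonging to encoder level i
        skip_grads = []
        for up, blk, c in zip(self.ups[::-1], self.dec[::-1],
                              self._skip_channels):
            g = blk.backward(g)
            skip_grads.append(g[:c])
            g = up.backward(g[c:])
        for i in range(len(self.enc) - 1, -1, -1):
            if i < len(self.pools):
                g = self.pools[i].backward(g)
                g = g + skip_grads[i]
            g = self.enc[i].backward(g)

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()


def build_unet(config: UNetConfig) -> UNet3D:
    """Construct a seeded network; identical configs (incl. seed) yield
    bit-identical initial parameters."""
    return UNet3D(config)


def predict_log_field(net: UNet3D, a_norm) -> np.ndarray:
    """Run the estimator on a normalized volume; returns the log field."""
    from .volume import Volume

    data = a_norm.data if isinstance(a_norm, Volume) else np.asarray(a_norm)
    return np.asarray(net.forward(data), dtype=float)
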