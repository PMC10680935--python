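"""Synthetic head phantoms with known multiplicative bias fields.

Real supervision for bias-field correction comes from running an
iterative reference algorithm over large T1w corpora.  For desk-scale
training and validation this module generates the same statistical
structure from scratch: a piecewise-near-constant "brain" of three
tissue classes (CSF, grey matter, white matter) inside a smooth
ellipsoidal head support, multiplied voxelwise by a strictly positive
smooth low-spatial-frequency field, with optional additive Gaussian
noise.  Every sample ships with its ground-truth corrected image, field,
and brain mask, so losses and metrics need no external data.

The generator emulates the *assumptions* of the correction model (smooth
multiplicative corruption of near-piecewise-constant anatomy); it does
not attempt anatomical realism, Rician noise, or partial-volume effects.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .core import Sample
from .volume import Mask, Volume

__all__ = [
    "PhantomSpec",
    "FieldSpec",
    "generate_phantom",
    "generate_bias_field",
    "generate_sample",
    "generate_dataset",
    "dataset_manifest",
]


@dataclasses.dataclass
class PhantomSpec:
    """Geometry and intensity layout of the synthetic head.

    ``tissue_means`` are the CSF/GM/WM class intensities on the [0, 1]
    normalized scale; ``inner_radii`` place the WM and GM ellipsoids as
    fractions of the head semi-axes (CSF fills the remainder of the
    support).  ``geom_jitter`` randomizes semi-axes and center per seed
    so a dataset is not 64 copies of one head.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    tissue_means: tuple[float, float, float] = (0.15, 0.45, 0.75)
    semi_axes: tuple[float, float, float] = (0.42, 0.40, 0.38)
    inner_radii: tuple[float, float] = (0.60, 0.85)  # WM, GM fractions
    texture_sd: float = 0.02
    noise_sd: float = 0.01
    geom_jitter: float = 0.05

    def __post_init__(self) -> None:
        tm = self.tissue_means
        if not (0 < tm[0] < tm[1] < tm[2] < 1):
            raise ValueError("tissue means must be strictly increasing in (0,1)")
        if any(not (0 < a <= 0.5) for a in self.semi_axes):
            raise ValueError("semi-axes must be fractions in (0, 0.5]")
        if not (0 < self.inner_radii[0] < self.inner_radii[1] < 1):
            raise ValueError("inner radii must satisfy 0 < wm < gm < 1")
        if self.texture_sd < 0 or self.noise_sd < 0 or self.geom_jitter < 0:
            raise ValueError("sd/jitter parameters must be nonnegative")


@dataclasses.dataclass
class FieldSpec:
    """Statistical family of the simulated log bias field.

    ``log_amplitude`` is the half-range of log b after rescaling; the
    default 0.3 gives fields spanning roughly [0.74, 1.35] — visible
    shading without destroying tissue contrast.
    """

    family: str = "gauss_random_field"
    log_amplitude: float = 0.3
    correlation_length: float = 12.0
    poly_order: int = 2
    control_points: int = 4

    def __post_init__(self) -> None:
        if self.family not in ("gauss_random_field", "polynomial", "bspline"):
            raise ValueError(f"unknown field family {self.family!r}")
        if self.log_amplitude <= 0:
            raise ValueError("log_amplitude must be positive")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")


def _ellipsoid(shape, center, semi_axes_vox) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes_vox))
    return r2 <= 1.0


def generate_phantom(spec: PhantomSpec, seed: int = 0):
    """Nested-ellipsoid brain: returns (corrected-truth Volume, Mask, labels).

    Labels: 0 background, 1 CSF, 2 GM, 3 WM.  Class intensities are the
    spec means plus seeded within-tissue jitter (``texture_sd``), clipped
    to stay positive.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in spec.shape)
    center = np.array([(n - 1) / 2.0 for n in shape])
    axes = np.array(spec.semi_axes) * np.array(shape)
    if spec.geom_jitter > 0:
        axes = axes * (1.0 + rng.uniform(-spec.geom_jitter, spec.geom_jitter, 3))
        center = center + rng.uniform(-spec.geom_jitter, spec.geom_jitter, 3) \
            * np.array(shape) * 0.25
    if np.any(axes < 2):
        raise ValueError("degenerate geometry: semi-axes below 2 voxels")

    support = _ellipsoid(shape, center, axes)
    gm = _ellipsoid(shape, center, axes * spec.inner_radii[1])
    wm = _ellipsoid(shape, center, axes * spec.inner_radii[0])
    labels = np.zeros(shape, dtype=np.uint8)
    labels[support] = 1          # CSF shell
    labels[gm] = 2
    labels[wm] = 3

    u = np.zeros(shape, dtype=float)
    for lab, mean in zip((1, 2, 3), spec.tissue_means):
        m = labels == lab
        u[m] = mean + spec.texture_sd * rng.standard_normal(int(m.sum()))
    u = np.clip(u, 1e-3, None) * (labels > 0)
    return Volume(u), Mask(support), labels


def _rescale_log(g: np.ndarray, amp: float) -> np.ndarray:
    peak = np.max(np.abs(g))
    if peak == 0:
        return g
    return g * (amp / peak)


def generate_bias_field(spec: FieldSpec, shape, seed: int = 0) -> Volume:
    """Strictly positive smooth field b = exp(g), max |log b| = log_amplitude."""
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    if spec.family == "gauss_random_field":
        g = rng.standard_normal(shape)
        g = ndimage.gaussian_filter(g, spec.correlation_length, mode="reflect")
        g -= g.mean()
    elif spec.family == "polynomial":
        coords = np.meshgrid(*[np.linspace(-1, 1, n) for n in shape],
                             indexing="ij")
        g = np.zeros(shape)
        for px in range(spec.poly_order + 1):
            for py in range(spec.poly_order + 1 - px):
                for pz in range(spec.poly_order + 1 - px - py):
                    if px == py == pz == 0:
                        continue
                    g += rng.normal() * coords[0] ** px * coords[1] ** py \
                        * coords[2] ** pz
    else:  # bspline: coarse random control mesh, cubic-interpolated up
        c = max(2, int(spec.control_points))
        mesh = rng.standard_normal((c, c, c))
        zoom = [n / c for n in shape]
        g = ndimage.zoom(mesh, zoom, order=3, mode="nearest",
                         grid_mode=True)
        g -= g.mean()
    g = _rescale_log(g, spec.log_amplitude)
    return Volume(np.exp(g))


def generate_sample(pspec: PhantomSpec, fspec: FieldSpec, seed: int = 0) -> Sample:
    """Full forward model: a = u * b (+ additive noise), with mask."""
    rng = np.random.default_rng(seed)
    # independent sub-seeds so phantom/field draws cannot collide
    s_phantom, s_field, s_noise = rng.integers(0, 2 ** 31 - 1, size=3)
    u, mask, _ = generate_phantom(pspec, int(s_phantom))
    b = generate_bias_field(fspec, pspec.shape, int(s_field))
    a = u.data * b.data
    if pspec.noise_sd > 0:
        noise_rng = np.random.default_rng(int(s_noise))
        a = a + pspec.noise_sd * noise_rng.standard_normal(a.shape)
    return Sample(acquired=Volume(a), corrected_truth=u, field_truth=b,
                  mask=mask)


def generate_dataset(n: int, pspec: PhantomSpec, fspec: FieldSpec,
                     seed: int = 0):
    """n samples with per-sample derived seeds; returns (samples, manifest).

    The manifest records every spec field and per-sample seed, so
    regenerating from it is bit-identical.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sample_seeds = [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]
    samples = [generate_sample(pspec, fspec, s) for s in sample_seeds]
    manifest = dataset_manifest(n, pspec, fspec, seed, sample_seeds)
    return samples, manifest


def dataset_manifest(n, pspec, fspec, seed, sample_seeds) -> dict:
    return {
        "n": n,
        "seed": seed,
        "sample_seeds": sample_seeds,
        "phantom": dataclasses.asdict(pspec),
        "field": dataclasses.asdict(fspec),
    }


def dataset_from_manifest(manifest: dict):
    """Regenerate the exact dataset a manifest describes."""
    pspec = PhantomSpec(**{**manifest["phantom"],
                           "shape": tuple(manifest["phantom"]["shape"])})
    fd = dict(manifest["field"])
    fspec = FieldSpec(**fd)
    samples = [generate_sample(pspec, fspec, int(s))
               for s in manifest["sample_seeds"]]
    return samples, pspec, fspec
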