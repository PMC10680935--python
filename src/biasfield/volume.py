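"""NIfTI volume I/O and the fixed preprocessing chain.

A T1-weighted input volume passes through: resampling to a common voxel
size (2 mm isotropic by default), centered padding/cropping to a fixed
lattice (128^3 by default), and 99th-percentile min-max normalization
clipped to [0, 1].  Every step writes its parameters into a
:class:`PreprocessRecord` so a bias field predicted on the preprocessed
grid can be mapped back to the native grid for correction at full
resolution.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu

__all__ = [
    "Volume",
    "Mask",
    "PreprocessRecord",
    "read_volume",
    "write_volume",
    "resample_volume",
    "pad_crop_to_shape",
    "minmax_normalize",
    "compute_brain_mask",
    "restore_to_native",
    "preprocess",
]


@dataclasses.dataclass
class Volume:
    """A 3D scalar lattice with voxel spacing and a voxel-to-world affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities in arbitrary physical units.
    spacing : tuple of float
        Per-axis voxel size in mm; all entries strictly positive.
    affine : ndarray, shape (4, 4), optional
        Voxel-index-to-world map.  Defaults to a diagonal affine built
        from ``spacing``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"Volume data must have exactly 3 axes, got {self.data.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume data contains non-finite values")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    def copy_with(self, data: np.ndarray) -> "Volume":
        """New Volume with the same grid metadata but different data."""
        return Volume(data, self.spacing, self.affine.copy())


@dataclasses.dataclass
class Mask:
    """A binary lattice aligned with a :class:`Volume`."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("Mask data must have exactly 3 axes")

    @property
    def count(self) -> int:
        """Number of foreground voxels (``N`` in masked losses/metrics)."""
        return int(self.data.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)


@dataclasses.dataclass
class PreprocessRecord:
    """Invertible log of the preprocessing chain applied to one volume.

    ``pad_offsets``/``crop_offsets`` are per-axis (before, after) voxel
    counts; ``norm_xmax`` is the 99th intensity percentile used as the
    normalization ceiling (``Xmin`` is fixed at 0).
    """

    source_shape: tuple[int, int, int] | None = None
    source_spacing: tuple[float, float, float] | None = None
    source_affine: np.ndarray | None = None
    pad_offsets: tuple[tuple[int, int], ...] | None = None
    crop_offsets: tuple[tuple[int, int], ...] | None = None
    norm_xmax: float | None = None
    norm_xmin: float = 0.0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_volume(path) -> Volume:
    """Read a 3D NIfTI-1/2 file without reorientation."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asarray(data, dtype=np.float64), spacing, np.asarray(img.affine))


def write_volume(vol: Volume, path, dtype=None) -> None:
    """Write a :class:`Volume` as NIfTI; data round-trips bit-exactly.

    Masks should be written with ``dtype=np.uint8``.
    """
    if not np.all(np.isfinite(vol.data)):
        raise ValueError("refusing to write non-finite data")
    path = Path(path)
    data = vol.data if dtype is None else vol.data.astype(dtype)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: Mask, like: Volume, path) -> None:
    """Write a mask as unsigned 8-bit NIfTI on ``like``'s grid."""
    write_volume(like.copy_with(mask.data.astype(np.uint8)), path, dtype=np.uint8)


# ---------------------------------------------------------------------------
# Preprocessing chain
# ---------------------------------------------------------------------------

def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.floor(np.abs(x) + 0.5) * np.sign(x)


def resample_volume(vol: Volume, target_spacing, mode: str = "linear") -> Volume:
    """Resample to ``target_spacing`` (mm), preserving the physical extent.

    Output shape per axis is ``round(shape * spacing / target)`` with
    round-half-away-from-zero.  ``mode`` is ``"linear"`` (trilinear, for
    images and fields) or ``"nearest"`` (for masks).
    """
    target = np.asarray(target_spacing, dtype=float)
    if target.shape != (3,):
        target = np.broadcast_to(target, (3,)).astype(float)
    if np.any(target <= 0):
        raise ValueError(f"target spacing must be positive, got {tuple(target)}")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation mode {mode!r}")

    src = np.asarray(vol.spacing)
    out_shape = _round_half_away(np.array(vol.shape) * src / target).astype(int)
    out_shape = np.maximum(out_shape, 1)

    # Cell-centered sampling: output voxel i sits at physical (i+0.5)*t,
    # i.e. source index (i+0.5)*t/s - 0.5.
    coords = np.meshgrid(
        *[(np.arange(n) + 0.5) * t / s - 0.5
          for n, t, s in zip(out_shape, target, src)],
        indexing="ij",
    )
    order = 1 if mode == "linear" else 0
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float), np.stack(coords), order=order,
        mode="nearest",
    )

    scale = target / src
    affine = vol.affine.copy()
    affine[:3, :3] = affine[:3, :3] * scale[np.newaxis, :]
    shift = (scale / 2.0) - 0.5
    affine[:3, 3] = vol.affine[:3, 3] + vol.affine[:3, :3] @ shift
    return Volume(out, tuple(target), affine)


def pad_crop_to_shape(vol: Volume, shape=(128, 128, 128), fill: float = 0.0):
    """Pad and/or crop to an exact shape, content centered.

    Excess is split floor/ceil per axis; the returned record stores both
    pad and crop offsets so the operation is invertible.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 1 for s in shape):
        raise ValueError(f"target shape entries must be >= 1, got {shape}")
    data = vol.data
    pads, crops = [], []
    for ax, (cur, tgt) in enumerate(zip(data.shape, shape)):
        if tgt >= cur:
            before = (tgt - cur) // 2
            pads.append((before, tgt - cur - before))
            crops.append((0, 0))
        else:
            before = (cur - tgt) // 2
            crops.append((before, cur - tgt - before))
            pads.append((0, 0))
    data = data[tuple(slice(c0, data.shape[i] - c1)
                      for i, (c0, c1) in enumerate(crops))]
    data = np.pad(data, pads, mode="constant", constant_values=fill)
    record = PreprocessRecord(
        source_shape=vol.shape,
        source_spacing=vol.spacing,
        pad_offsets=tuple(pads),
        crop_offsets=tuple(crops),
    )
    affine = vol.affine.copy()
    offset = np.array([c[0] - p[0] for p, c in zip(pads, crops)], dtype=float)
    affine[:3, 3] = vol.affine[:3, 3] + vol.affine[:3, :3] @ offset
    return Volume(data, vol.spacing, affine), record


def invert_pad_crop(vol: Volume, record: PreprocessRecord,
                    pad_mode: str = "edge") -> Volume:
    """Undo :func:`pad_crop_to_shape`: strip padding, refill crops.

    Cropped margins are refilled by edge replication by default, which is
    the right choice for smooth multiplicative fields.
    """
    if record.pad_offsets is None or record.crop_offsets is None:
        raise ValueError("record has no pad/crop information")
    expected = tuple(
        record.source_shape[i] + sum(record.pad_offsets[i])
        - sum(record.crop_offsets[i])
        for i in range(3)
    )
    if vol.shape != expected:
        raise ValueError(
            f"volume shape {vol.shape} inconsistent with record (expected {expected})"
        )
    data = vol.data
    data = data[tuple(
        slice(p0, data.shape[i] - p1)
        for i, (p0, p1) in enumerate(record.pad_offsets)
    )]
    data = np.pad(data, record.crop_offsets, mode=pad_mode)
    affine = vol.affine.copy()
    offset = np.array([p[0] - c[0] for p, c in
                       zip(record.pad_offsets, record.crop_offsets)], dtype=float)
    affine[:3, 3] = vol.affine[:3, 3] + vol.affine[:3, :3] @ offset
    return Volume(data, vol.spacing, affine)


def minmax_normalize(vol: Volume):
    """Scale intensities by the 99th percentile and clip to [0, 1].

    Implements X -> clip(X / p99(X), 0, 1): the minimum is fixed at 0 and
    the ceiling is the 99th intensity percentile over all voxels (linear
    interpolation), so the brightest 1% of voxels saturate at 1.
    """
    data = np.asarray(vol.data, dtype=float)
    xmax = float(np.percentile(data, 99))
    if xmax <= 0:
        raise ValueError("degenerate image: 99th percentile is not positive")
    out = np.clip(data / xmax, 0.0, 1.0)
    record = PreprocessRecord(source_shape=vol.shape, source_spacing=vol.spacing,
                              norm_xmax=xmax, norm_xmin=0.0)
    return vol.copy_with(out), record


def compute_brain_mask(vol: Volume) -> Mask:
    """Foreground mask: Otsu threshold, largest 6-connected component,
    morphological hole fill.

    A T1w head histogram is multimodal (background, CSF, GM, WM), which
    misleads a binary Otsu into cutting *within* the head; the lowest
    threshold of a four-class Otsu separates background from everything
    else instead.  Falls back to fewer classes when the image has too few
    distinct intensities.  Intended for normalized images in [0, 1]; used
    only to restrict losses and metrics to tissue, so clinical-grade
    skull stripping is not needed.
    """
    data = np.asarray(vol.data, dtype=float)
    if not np.any(data > 0):
        raise ValueError("empty mask: volume has no positive voxels")
    thr = None
    for classes in (4, 3):
        try:
            thr = float(threshold_multiotsu(data, classes=classes)[0])
            break
        except ValueError:  # fewer distinct gray levels than classes
            continue
    if thr is None:
        thr = float(threshold_otsu(data))
    fg = data > thr
    if not fg.any():
        raise ValueError("empty mask: Otsu threshold removed all voxels")
    labels, nlab = ndimage.label(fg)  # default structure = 6-connectivity
    if nlab > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, nlab + 1))
        fg = labels == (int(np.argmax(sizes)) + 1)
    fg = ndimage.binary_fill_holes(fg)
    return Mask(fg)


def restore_to_native(field: Volume, record: PreprocessRecord,
                      native: Volume) -> Volume:
    """Map a field from the preprocessed grid back to the native grid.

    Inverse pad/crop, then linear resampling onto the native lattice; a
    bias field is smooth by construction, so trilinear interpolation is
    adequate.
    """
    unpadded = invert_pad_crop(field, record)
    src = np.asarray(field.spacing)
    tgt = np.asarray(native.spacing)
    # Sample the unpadded (resampled-grid) field at native cell centers.
    coords = np.meshgrid(
        *[(np.arange(n) + 0.5) * t / s - 0.5
          for n, t, s in zip(native.shape, tgt, src)],
        indexing="ij",
    )
    out = ndimage.map_coordinates(np.asarray(unpadded.data, dtype=float),
                                  np.stack(coords), order=1, mode="nearest")
    return Volume(out, native.spacing, native.affine.copy())


def preprocess(vol: Volume, target_spacing=(2.0, 2.0, 2.0),
               shape=(128, 128, 128)):
    """Full chain: resample -> pad/crop -> normalize -> brain mask.

    Returns ``(normalized Volume, Mask, PreprocessRecord)``.  The record's
    pad/crop offsets are relative to the resampled grid (which is what
    ``invert_pad_crop`` needs); the native grid itself travels with the
    native Volume handed to :func:`restore_to_native`.
    """
    res = resample_volume(vol, target_spacing, mode="linear")
    padded, rec = pad_crop_to_shape(res, shape)
    norm, nrec = minmax_normalize(padded)
    rec.source_affine = vol.affine.copy()
    rec.norm_xmax = nrec.norm_xmax
    mask = compute_brain_mask(norm)
    return norm, mask, rec
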