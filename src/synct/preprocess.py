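"""Preprocessing chain: resampling, heart-ROI cropping, HU windowing and
normalization, and paired random cropping for training.

The clinical chain resamples to 0.9 x 0.9 x 1.0 mm, crops a
384 x 384 x 150 box near the heart, clips intensities to the
[-150, 500] HU contrast window, and feeds randomly cropped 352 x 352
axial slices to the model.  No other augmentation is applied.  Every
geometric transform applied to a pair is applied identically to both
members, so registration is never broken downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CTVolume, Grid, PairedSample


@dataclass(frozen=True)
class PreprocessConfig:
    target_spacing: tuple[float, float, float] = (0.9, 0.9, 1.0)
    roi_size: tuple[int, int, int] = (384, 384, 150)
    window: tuple[float, float] = (-150.0, 500.0)
    train_crop: int | None = 352
    normalized_range: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self):
        if self.window[0] >= self.window[1]:
            raise ValueError("window low must be < high")
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target_spacing must be positive")
        if self.train_crop is not None and self.train_crop > min(self.roi_size[:2]):
            raise ValueError("train_crop exceeds in-plane ROI size")

    @property
    def window_width(self):
        return self.window[1] - self.window[0]


def resample(volume: CTVolume, target_spacing) -> CTVolume:
    """Trilinear resample onto a grid of the given spacing.

    Output shape is ``round(extent / target_spacing)``; the origin stays
    at the first voxel center.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive")
    src = volume.grid
    new_shape = tuple(
        max(1, int(round(e / t))) for e, t in zip(src.extent, target_spacing))
    if new_shape == src.shape and np.allclose(target_spacing, src.spacing):
        return volume.copy()
    idx = [np.arange(n) * t / s for n, t, s in
           zip(new_shape, target_spacing, src.spacing)]
    I, J, K = np.meshgrid(*idx, indexing="ij")
    out = ndimage.map_coordinates(volume.voxels, np.stack([I, J, K]),
                                  order=1, mode="nearest")
    return CTVolume(out.astype(np.float32),
                    Grid(new_shape, target_spacing, src.origin))


def crop_roi(volume: CTVolume, center, size,
             pad_value: float | None = None,
             window=(-150.0, 500.0)) -> CTVolume:
    """Half-open box of ``size`` voxels centered at voxel index ``center``.

    Regions outside the source are padded with ``pad_value`` (default:
    the contrast window's lower bound).
    """
    if pad_value is None:
        pad_value = float(window[0])
    center = tuple(int(v) for v in center)
    size = tuple(int(v) for v in size)
    start = tuple(c - s // 2 for c, s in zip(center, size))
    out = np.full(size, pad_value, dtype=np.float32)
    src_sl, dst_sl = [], []
    for a in range(3):
        s0 = max(start[a], 0)
        s1 = min(start[a] + size[a], volume.voxels.shape[a])
        if s0 >= s1:
            raise IndexError(f"ROI does not intersect volume along axis {a}")
        src_sl.append(slice(s0, s1))
        dst_sl.append(slice(s0 - start[a], s1 - start[a]))
    out[tuple(dst_sl)] = volume.voxels[tuple(src_sl)]
    origin = tuple(volume.grid.origin[a] + start[a] * volume.grid.spacing[a]
                   for a in range(3))
    return CTVolume(out, Grid(size, volume.grid.spacing, origin))


def window_and_normalize(volume: CTVolume, config: PreprocessConfig) -> CTVolume:
    """Clip to the contrast window, then map affinely onto the model range."""
    lo, hi = config.window
    a, b = config.normalized_range
    clipped = np.clip(volume.voxels, lo, hi)
    out = (clipped - lo) / (hi - lo) * (b - a) + a
    return CTVolume(out.astype(np.float32), volume.grid)


def denormalize(volume: CTVolume, config: PreprocessConfig) -> CTVolume:
    """Inverse of :func:`window_and_normalize` on the clipped range."""
    lo, hi = config.window
    a, b = config.normalized_range
    out = (np.clip(volume.voxels, a, b) - a) / (b - a) * (hi - lo) + lo
    return CTVolume(out.astype(np.float32), volume.grid)


def normalize_array(arr, config: PreprocessConfig):
    lo, hi = config.window
    a, b = config.normalized_range
    return ((np.clip(arr, lo, hi) - lo) / (hi - lo) * (b - a) + a).astype(np.float32)


def denormalize_array(arr, config: PreprocessConfig):
    lo, hi = config.window
    a, b = config.normalized_range
    return ((np.clip(arr, a, b) - a) / (b - a) * (hi - lo) + lo).astype(np.float32)


def random_crop_pair(nct_slice, cect_slice, crop: int, rng):
    """Crop the same random ``crop x crop`` window from both slices.

    The offset is uniform over all valid positions; applying one offset
    to both members preserves the pairing.
    """
    nct_slice = np.asarray(nct_slice)
    cect_slice = np.asarray(cect_slice)
    if nct_slice.shape != cect_slice.shape:
        raise ValueError("paired slices must share shape")
    h, w = nct_slice.shape
    if crop > h or crop > w:
        raise ValueError(f"crop {crop} larger than slice {nct_slice.shape}")
    oi = int(rng.integers(0, h - crop + 1))
    oj = int(rng.integers(0, w - crop + 1))
    return (nct_slice[oi:oi + crop, oj:oj + crop],
            cect_slice[oi:oi + crop, oj:oj + crop], (oi, oj))


def pad_to_multiple(arr2d, multiple=32, value=-1.0):
    """Symmetrically pad a 2-D slice so both sides divide ``multiple``.

    Returns the padded slice and the slices needed to undo the padding.
    The generator's five down/up transitions require sides divisible by
    2^5 = 32.
    """
    h, w = arr2d.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    top, left = ph // 2, pw // 2
    out = np.pad(arr2d, ((top, ph - top), (left, pw - left)),
                 constant_values=value)
    return out, (slice(top, top + h), slice(left, left + w))


def heart_roi_center(volume: CTVolume, heart_mask=None):
    """ROI placement: heart-mask centroid when available, else the
    geometric center of the volume."""
    if heart_mask is not None and heart_mask.mask.any():
        com = ndimage.center_of_mass(heart_mask.mask)
        return tuple(int(round(c)) for c in com)
    return tuple(s // 2 for s in volume.voxels.shape)


def preprocess_pair(pair: PairedSample, config: PreprocessConfig,
                    center=None, heart_mask=None,
                    do_resample: bool = False) -> PairedSample:
    """Apply the full chain (optional resample, ROI crop, window+normalize)
    identically to both members of a pair."""
    nct, cect = pair.nct, pair.cect
    if do_resample:
        nct = resample(nct, config.target_spacing)
        cect = resample(cect, config.target_spacing)
    if center is None:
        center = heart_roi_center(nct, heart_mask)
    roi = tuple(min(r, s) for r, s in zip(config.roi_size, nct.voxels.shape))
    nct = crop_roi(nct, center, roi, window=config.window)
    cect = crop_roi(cect, center, roi, window=config.window)
    nct = window_and_normalize(nct, config)
    cect = window_and_normalize(cect, config)
    return PairedSample(nct, cect)
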