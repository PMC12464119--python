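"""Preprocessing and augmentation applied consistently to image/label pairs.

Spatial transforms (axis flips, axis-aligned 90-degree rotations) are voxel
permutations, applied identically to image and labels, so the label value set
is always preserved exactly.  Intensity transforms (multiplicative scale,
additive shift) touch only the image.  All randomness flows from explicit
seeds.  Free-angle rotation with nearest-neighbour label resampling exists
behind a flag but is off by default: label-exact transforms keep the pipeline
deterministic and artefact-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

from .volume_io import LabelVolume, Volume

__all__ = ["AugmentConfig", "augment_pair", "sample_patch", "pad_to_shape"]

_AXIS_PAIRS = ((0, 1), (0, 2), (1, 2))


@dataclass(frozen=True)
class AugmentConfig:
    flip_prob: tuple[float, float, float] = (0.5, 0.5, 0.5)
    rotate90_prob: tuple[float, float, float] = (0.0, 0.0, 0.5)  # per axis pair
    intensity_scale_range: tuple[float, float] = (0.9, 1.1)
    intensity_shift_range: tuple[float, float] = (-0.1, 0.1)
    free_rotation_max_deg: float = 0.0   # >0 enables free-angle rotation
    seed: int = 0

    def __post_init__(self):
        for p in (*self.flip_prob, *self.rotate90_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.intensity_scale_range[0] <= 0:
            raise ValueError("intensity scale range must be positive")


def _check_same_grid(v: Volume, lv: LabelVolume) -> None:
    if v.shape != lv.shape:
        raise ValueError(f"image and labels must share a grid, got "
                         f"{v.shape} vs {lv.shape}")


def augment_pair(v: Volume, lv: LabelVolume, cfg: AugmentConfig,
                 rng: np.random.Generator | None = None
                 ) -> tuple[Volume, LabelVolume]:
    """Apply one random draw of the configured augmentations to the pair."""
    _check_same_grid(v, lv)
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    img = v.data.astype(np.float32, copy=True)
    lab = lv.labels.copy()

    for axis in range(3):
        if rng.random() < cfg.flip_prob[axis]:
            img = np.flip(img, axis=axis)
            lab = np.flip(lab, axis=axis)
            log.debug("augment: flip axis=%d", axis)
    for pair_i, pair in enumerate(_AXIS_PAIRS):
        if rng.random() < cfg.rotate90_prob[pair_i]:
            k = int(rng.integers(1, 4))
            img = np.rot90(img, k=k, axes=pair)
            lab = np.rot90(lab, k=k, axes=pair)
            log.debug("augment: rot90 k=%d axes=%s", k, pair)
    if cfg.free_rotation_max_deg > 0.0:
        angle = float(rng.uniform(-cfg.free_rotation_max_deg,
                                  cfg.free_rotation_max_deg))
        img = ndimage.rotate(img, angle, axes=(0, 1), reshape=False,
                             order=1, mode="nearest")
        lab = ndimage.rotate(lab, angle, axes=(0, 1), reshape=False,
                             order=0, mode="nearest")

    scale = float(rng.uniform(*cfg.intensity_scale_range))
    shift = float(rng.uniform(*cfg.intensity_shift_range))
    img = img * scale + shift
    log.debug("augment: scale=%.4f shift=%.4f", scale, shift)

    return (replace(v, data=np.ascontiguousarray(img)),
            replace(lv, labels=np.ascontiguousarray(lab)))


def pad_to_shape(arr: np.ndarray, target: tuple[int, int, int],
                 value: float = 0.0) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Symmetric padding up to `target` (no-op on axes already large enough).
    Returns the padded array and the per-axis pad widths used."""
    pads = []
    for a in range(3):
        deficit = max(0, target[a] - arr.shape[a])
        pads.append((deficit // 2, deficit - deficit // 2))
    if any(p != (0, 0) for p in pads):
        arr = np.pad(arr, pads, constant_values=value)
    return arr, pads


def sample_patch(v: Volume, lv: LabelVolume,
                 patch: tuple[int, int, int] = (64, 64, 64),
                 seed: int | None = None,
                 rng: np.random.Generator | None = None
                 ) -> tuple[Volume, LabelVolume]:
    """Random 3-D crop of exactly ``patch`` shape from an aligned pair.

    The crop origin is uniform over all valid positions.  Inputs smaller than
    the patch are first padded symmetrically (zeros for the image, background
    for the labels).
    """
    _check_same_grid(v, lv)
    rng = rng if rng is not None else np.random.default_rng(seed)
    img, _ = pad_to_shape(v.data, patch, 0.0)
    lab, _ = pad_to_shape(lv.labels, patch, 0)
    origin = tuple(int(rng.integers(0, img.shape[a] - patch[a] + 1))
                   for a in range(3))
    sl = tuple(slice(o, o + p) for o, p in zip(origin, patch))
    return (replace(v, data=np.ascontiguousarray(img[sl])),
            replace(lv, labels=np.ascontiguousarray(lab[sl])))
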