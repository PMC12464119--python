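"""Whole-volume prediction: spacing check and resampling, overlapping
sliding-window tiling with blended per-window class scores, argmax decoding,
and instance/semantic export.

The input is resampled to the model's native spacing when its own spacing
differs by more than 1% (relative), normalised to [0, 1], tiled into
overlapping windows whose scores are blended with Gaussian (default) or
constant weights — the blending weights form a partition of unity at every
voxel, including borders — decoded by per-voxel argmax (ties break toward the
lower class index, so background wins an all-equal tie), and finally mapped
back onto the caller's original voxel grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn
from .label_scheme import default_scheme, merge_to_semantic
from .model import OralSegNet
from .transforms import pad_to_shape
from .volume_io import LabelVolume, Volume, normalize_intensity, resample_to_spacing

__all__ = ["InferenceConfig", "predict_volume", "decode_labels",
           "sliding_window_scores", "blend_weights"]


@dataclass(frozen=True)
class InferenceConfig:
    roi: tuple[int, int, int, int, int, int] | None = None   # x0,y0,z0,x1,y1,z1
    window: tuple[int, int, int] = (64, 64, 64)
    overlap: float = 0.5
    blend: str = "gaussian"              # gaussian | constant
    target_spacing: float | tuple | None = 0.3
    spacing_rtol: float = 0.01
    output_mode: str = "instance"        # instance | semantic

    def __post_init__(self):
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if self.blend not in ("gaussian", "constant"):
            raise ValueError(f"unknown blend mode {self.blend!r}")
        if self.output_mode not in ("instance", "semantic"):
            raise ValueError(f"unknown output mode {self.output_mode!r}")


def blend_weights(window: tuple[int, int, int], blend: str) -> np.ndarray:
    """Per-voxel window weight: Gaussian bump (sigma = window/8) or ones."""
    if blend == "constant":
        return np.ones(window, dtype=np.float32)
    grids = []
    for w in window:
        x = np.arange(w, dtype=np.float32) - (w - 1) / 2.0
        sigma = max(w / 8.0, 1.0)
        grids.append(np.exp(-0.5 * (x / sigma) ** 2))
    out = grids[0][:, None, None] * grids[1][None, :, None] * grids[2][None, None, :]
    return np.maximum(out, 1e-4).astype(np.float32)


def _window_origins(dim: int, win: int, overlap: float) -> list[int]:
    if dim <= win:
        return [0]
    step = max(1, int(round(win * (1.0 - overlap))))
    origins = list(range(0, dim - win + 1, step))
    if origins[-1] != dim - win:
        origins.append(dim - win)
    return origins


def sliding_window_scores(data: np.ndarray, model: OralSegNet,
                          window: tuple[int, int, int] = (64, 64, 64),
                          overlap: float = 0.5,
                          blend: str = "gaussian") -> np.ndarray:
    """Blended per-class scores (C, D, H, W) for an arbitrary-size volume.

    Volumes smaller than one window are zero-padded symmetrically and the
    padding is cropped from the returned scores.
    """
    orig_shape = data.shape
    padded, pads = pad_to_shape(np.asarray(data, dtype=np.float32), window, 0.0)
    shape = padded.shape
    weights = blend_weights(window, blend)
    acc = None
    wsum = np.zeros(shape, dtype=np.float32)
    for ox in _window_origins(shape[0], window[0], overlap):
        for oy in _window_origins(shape[1], window[1], overlap):
            for oz in _window_origins(shape[2], window[2], overlap):
                sl = (slice(ox, ox + window[0]), slice(oy, oy + window[1]),
                      slice(oz, oz + window[2]))
                scores = model.predict_scores(padded[sl])[0]  # (C, ...)
                if acc is None:
                    acc = np.zeros((scores.shape[0], *shape), dtype=np.float32)
                acc[(slice(None), *sl)] += scores * weights
                wsum[sl] += weights
    acc /= wsum  # weights tile the grid, so wsum > 0 everywhere
    crop = tuple(slice(p[0], p[0] + s) for p, s in zip(pads, orig_shape))
    return acc[(slice(None), *crop)]


def decode_labels(scores: np.ndarray, spacing=(1.0, 1.0, 1.0),
                  origin=(0.0, 0.0, 0.0)) -> LabelVolume:
    """Voxelwise argmax over the class axis of (C, D, H, W); ties break toward
    the lower class index (background = class 0)."""
    labels = np.argmax(scores, axis=0).astype(np.int16)
    return LabelVolume(labels=labels, spacing=spacing, origin=origin)


def _resample_labels_to_grid(labels: np.ndarray, from_spacing,
                             to_shape, to_spacing) -> np.ndarray:
    """Nearest-neighbour resample onto an explicit target grid (exact shape)."""
    coords = np.meshgrid(
        *[(np.arange(n) + 0.5) * to_spacing[a] / from_spacing[a] - 0.5
          for a, n in enumerate(to_shape)], indexing="ij")
    return ndimage.map_coordinates(labels, np.stack(coords), order=0,
                                   mode="nearest")


def predict_volume(v: Volume, model: OralSegNet,
                   cfg: InferenceConfig = InferenceConfig(),
                   already_normalized: bool = False) -> LabelVolume:
    """Segment a whole volume; the output label grid is identical to the
    input grid."""
    work = v
    resampled = False
    if cfg.target_spacing is not None:
        tgt = cfg.target_spacing
        tgt = (tgt,) * 3 if np.isscalar(tgt) else tuple(tgt)
        rel = np.abs(np.array(v.spacing) - np.array(tgt)) / np.array(tgt)
        if np.any(rel > cfg.spacing_rtol):
            work = resample_to_spacing(v, tgt, mode="continuous")
            resampled = True
    if not already_normalized:
        work = normalize_intensity(work)

    data = work.data
    if cfg.roi is not None:
        x0, y0, z0, x1, y1, z1 = cfg.roi
        if not (0 <= x0 < x1 <= data.shape[0] and 0 <= y0 < y1 <= data.shape[1]
                and 0 <= z0 < z1 <= data.shape[2]):
            raise ValueError(f"ROI {cfg.roi} outside the volume {data.shape}")
        sub = data[x0:x1, y0:y1, z0:z1]
    else:
        sub = data

    scores = sliding_window_scores(sub, model, cfg.window, cfg.overlap,
                                   cfg.blend)
    sub_labels = np.argmax(scores, axis=0).astype(np.int16)

    labels = np.zeros(data.shape, dtype=np.int16)
    if cfg.roi is not None:
        labels[x0:x1, y0:y1, z0:z1] = sub_labels
    else:
        labels = sub_labels

    if resampled:
        labels = _resample_labels_to_grid(labels, work.spacing, v.shape,
                                          v.spacing)
    out = LabelVolume(labels=labels, spacing=v.spacing, origin=v.origin,
                      axis_orientation=v.axis_orientation)
    if cfg.output_mode == "semantic":
        return merge_to_semantic(out, default_scheme())
    return out
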