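"""Volumes, label volumes, file IO (NIfTI / NRRD), resampling and intensity
normalisation.

A :class:`Volume` is a 3-D scalar grid plus spacing/origin metadata.  The
internal canonical axis orientation is RAS; LPS files (the ITK/NRRD default)
are reoriented on read and restored on write, so voxel-level code never sees
mixed conventions.  Only axis-aligned orientations are supported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .label_scheme import LabelScheme, default_scheme

__all__ = ["Volume", "LabelVolume", "read_volume", "write_volume",
           "read_label_volume", "write_label_volume", "resample_to_spacing",
           "normalize_intensity", "FormatError"]


class FormatError(ValueError):
    """Raised for unreadable files or unsupported dimensionality."""


def _validate_grid(data: np.ndarray, spacing) -> None:
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D volume, got {data.ndim}-D data "
                          f"with shape {data.shape}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")


@dataclass
class Volume:
    """3-D scalar image with axis-aligned geometry (spacing in mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_orientation: str = "RAS"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _validate_grid(self.data, self.spacing)
        if self.axis_orientation not in ("RAS", "LPS"):
            raise ValueError(f"axis_orientation must be RAS or LPS, "
                             f"got {self.axis_orientation!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """3-D integer label map on the same grid conventions as :class:`Volume`."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_orientation: str = "RAS"
    scheme_ref: str = "oralseg-36"
    scheme: LabelScheme | None = field(default=None, repr=False)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volumes must hold integer data")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _validate_grid(self.labels, self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def present_classes(self) -> np.ndarray:
        vals = np.unique(self.labels)
        return vals[vals != 0]


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_NRRD_SUFFIXES = (".nrrd", ".seg.nrrd")


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(_NIFTI_SUFFIXES)


def _is_nrrd(path: Path) -> bool:
    return path.name.endswith(_NRRD_SUFFIXES)


def _read_any(path: str | Path) -> tuple[np.ndarray, tuple, tuple, str]:
    """Returns (data[x,y,z], spacing, origin, orientation-as-read)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        try:
            img = nib.load(str(path))
            data = np.asarray(img.dataobj)
        except Exception as e:  # truncated / malformed
            raise FormatError(f"cannot read NIfTI file {path}: {e}") from e
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        if data.ndim != 3:
            raise FormatError(f"{path}: expected 3-D, file is {data.ndim}-D")
        affine = img.affine
        spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in affine[:3, 3])
        # nibabel affines are RAS; detect axis flips (LPS-style storage)
        diag = np.diag(affine[:3, :3])
        orient = "RAS" if (diag[0] >= 0 and diag[1] >= 0) else "LPS"
        return data, spacing, origin, orient
    if _is_nrrd(path):
        try:
            img = sitk.ReadImage(str(path))
        except Exception as e:
            raise FormatError(f"cannot read NRRD file {path}: {e}") from e
        if img.GetDimension() != 3:
            raise FormatError(f"{path}: expected 3-D, file is "
                              f"{img.GetDimension()}-D")
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        data = np.ascontiguousarray(arr.transpose(2, 1, 0))
        spacing = tuple(float(s) for s in img.GetSpacing())
        origin = tuple(float(o) for o in img.GetOrigin())
        return data, spacing, origin, "LPS"  # ITK world frame is LPS
    raise FormatError(f"unsupported file format: {path.name} "
                      f"(expected {_NIFTI_SUFFIXES + _NRRD_SUFFIXES})")


def _to_ras(data: np.ndarray, origin: tuple, orient: str):
    """Flip the first two axes of LPS-stored data into canonical RAS."""
    if orient == "RAS":
        return data, origin
    data = data[::-1, ::-1, :].copy()
    return data, origin


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI or NRRD scalar volume; spacing comes from the header and
    intensities are untouched."""
    data, spacing, origin, orient = _read_any(path)
    data, origin = _to_ras(data, origin, orient)
    return Volume(data=data, spacing=spacing, origin=origin,
                  axis_orientation="RAS")


def read_label_volume(path: str | Path,
                      scheme: LabelScheme | None = None) -> LabelVolume:
    """Read an integer label map; a JSON sidecar ``<stem>.labels.json``
    (NIfTI) or embedded metadata is used for the scheme when present."""
    data, spacing, origin, orient = _read_any(path)
    data, origin = _to_ras(data, origin, orient)
    data = np.rint(data).astype(np.int16)
    if scheme is None:
        sidecar = _sidecar_path(Path(path))
        if sidecar.exists():
            scheme = LabelScheme.load(sidecar)
    return LabelVolume(labels=data, spacing=spacing, origin=origin,
                       axis_orientation="RAS", scheme=scheme)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii", ".seg.nrrd", ".nrrd"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".labels.json")
    return path.with_suffix(".labels.json")


def write_volume(v: Volume | LabelVolume, path: str | Path,
                 scheme: LabelScheme | None = None) -> Path:
    """Write to NIfTI or NRRD (chosen by extension).  Label maps get their
    label table embedded as NRRD key/value metadata or as a JSON sidecar for
    NIfTI."""
    path = Path(path)
    is_labels = isinstance(v, LabelVolume)
    data = v.labels if is_labels else v.data
    if is_labels and scheme is None:
        scheme = v.scheme or default_scheme()
    if _is_nifti(path):
        affine = np.diag(list(v.spacing) + [1.0])
        affine[:3, 3] = v.origin
        img = nib.Nifti1Image(np.asarray(data), affine)
        img.header.set_zooms(v.spacing)
        nib.save(img, str(path))
        if is_labels:
            scheme.save(_sidecar_path(path))
    elif _is_nrrd(path):
        # restore the ITK-native LPS storage (flip of the canonical RAS)
        arr = np.asarray(data)[::-1, ::-1, :]
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in v.spacing))
        img.SetOrigin(tuple(float(o) for o in v.origin))
        if is_labels:
            for e in scheme.entries:
                img.SetMetaData(f"Segment{e.index - 1}_Name", e.name)
                img.SetMetaData(f"Segment{e.index - 1}_LabelValue", str(e.index))
                img.SetMetaData(f"Segment{e.index - 1}_Color",
                                " ".join(f"{c / 255.0:.6f}" for c in e.color))
        sitk.WriteImage(img, str(path), useCompression=False)
    else:
        raise FormatError(f"unsupported output format: {path.name}")
    return path


def write_label_volume(lv: LabelVolume, path: str | Path,
                       scheme: LabelScheme | None = None) -> Path:
    return write_volume(lv, path, scheme=scheme)


# ---------------------------------------------------------------------------
# resampling and normalisation
# ---------------------------------------------------------------------------

def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def resample_to_spacing(v: Volume | LabelVolume,
                        target: tuple[float, float, float],
                        mode: str | None = None):
    """Resample to a target voxel spacing.

    Output shape per axis is round(shape*spacing/target), half away from zero,
    minimum 1.  Scalar volumes use trilinear interpolation (``continuous``),
    label maps always nearest-neighbour (``nearest``): requesting continuous
    interpolation of labels is a contract error.
    """
    target = tuple(float(t) for t in target)
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    is_labels = isinstance(v, LabelVolume)
    if mode is None:
        mode = "nearest" if is_labels else "continuous"
    if is_labels and mode != "nearest":
        raise ValueError("label volumes must be resampled with mode='nearest'")
    if mode not in ("continuous", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")

    data = v.labels if is_labels else v.data
    in_shape = np.array(data.shape, dtype=float)
    in_sp = np.array(v.spacing, dtype=float)
    out_sp = np.array(target, dtype=float)
    out_shape = np.maximum(_round_half_away(in_shape * in_sp / out_sp), 1).astype(int)

    if np.allclose(in_sp, out_sp) and tuple(out_shape) == data.shape:
        out = data.copy()
    else:
        # sample at voxel centres of the output grid, expressed in input voxels
        coords = np.meshgrid(*[( (np.arange(n) + 0.5) * out_sp[a] / in_sp[a] - 0.5)
                               for a, n in enumerate(out_shape)], indexing="ij")
        order = 0 if mode == "nearest" else 1
        out = ndimage.map_coordinates(
            data.astype(np.float32) if order else data,
            np.stack(coords), order=order, mode="nearest")
        if is_labels:
            out = out.astype(data.dtype)
        else:
            out = out.astype(np.float32)

    if is_labels:
        return replace(v, labels=out, spacing=target)
    return replace(v, data=out, spacing=target)


def normalize_intensity(v: Volume, clip_percentiles: tuple[float, float] | None = None) -> Volume:
    """Min-max normalise intensities to [0, 1].

    A constant volume maps to all zeros (no signal to rescale).  Optional
    percentile clipping (e.g. ``(0.5, 99.5)``) is applied before the min-max
    rescale; it is off by default.
    """
    data = v.data.astype(np.float32)
    if clip_percentiles is not None:
        lo, hi = np.percentile(data, clip_percentiles)
        data = np.clip(data, lo, hi)
    dmin, dmax = float(data.min()), float(data.max())
    if dmax - dmin == 0.0:
        out = np.zeros_like(data)
    else:
        out = (data - dmin) / (dmax - dmin)
    return replace(v, data=out)
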