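"""Core in-memory containers for volumes, label maps, and probability fields.

Conventions used throughout the package:

* Volumes are channel-first numpy arrays ``(C, X, Y, Z)``; label maps are
  integer arrays ``(X, Y, Z)`` with 0 = background.
* The first spatial axis (X) is the left-right anatomical axis of the
  stored orientation.
* Probability fields are ``(NC, X, Y, Z)`` arrays whose per-voxel class
  vector sums to one; one-hot label fields share that layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

LR_AXIS = 0  # spatial left-right axis


def _default_affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class VolumePair:
    """Two co-registered scalar 3-D channels (T1-like, T2-like)."""

    data: np.ndarray  # (2, X, Y, Z)
    spacing: tuple = (0.5, 0.5, 0.5)
    affine: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"VolumePair expects (C, X, Y, Z), got {self.data.shape}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self):
        return self.data.shape[1:]

    @property
    def n_channels(self):
        return self.data.shape[0]

    def copy(self) -> "VolumePair":
        return VolumePair(self.data.copy(), tuple(self.spacing), self.affine.copy())


@dataclass
class LabelMap:
    """Integer 3-D volume, values 0..NC-1 on the same grid as its VolumePair."""

    data: np.ndarray  # (X, Y, Z) integer
    spacing: tuple = (0.5, 0.5, 0.5)
    affine: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelMap values must be integers")
        if self.data.ndim != 3:
            raise ValueError(f"LabelMap expects (X, Y, Z), got {self.data.shape}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self):
        return self.data.shape

    def labels(self) -> np.ndarray:
        return np.unique(self.data)

    def copy(self) -> "LabelMap":
        return LabelMap(self.data.copy(), tuple(self.spacing), self.affine.copy())


def one_hot(labels: np.ndarray | LabelMap, n_classes: int) -> np.ndarray:
    """One-hot encode a label volume to a (NC, X, Y, Z) label field."""
    arr = labels.data if isinstance(labels, LabelMap) else np.asarray(labels)
    if arr.min() < 0 or arr.max() >= n_classes:
        raise ValueError(
            f"labels outside [0, {n_classes - 1}]: found range "
            f"[{arr.min()}, {arr.max()}]"
        )
    out = np.zeros((n_classes,) + arr.shape, dtype=np.float64)
    for c in range(n_classes):
        out[c] = arr == c
    return out


def is_probability_field(p: np.ndarray, tol: float = 1e-5) -> bool:
    """Check entries in [0, 1] and per-voxel class sums equal to 1."""
    p = np.asarray(p)
    if p.min() < -tol or p.max() > 1 + tol:
        return False
    return bool(np.allclose(p.sum(axis=0), 1.0, atol=tol))


# -- NIfTI I/O ----------------------------------------------------------------
def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), img.affine.copy()


def write_nifti(path, array: np.ndarray, affine: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(array), affine), str(path))


def load_volume_pair(t1_path, t2_path) -> VolumePair:
    t1, aff1 = read_nifti(t1_path)
    t2, aff2 = read_nifti(t2_path)
    if t1.shape != t2.shape:
        raise ValueError(f"channel grids differ: {t1.shape} vs {t2.shape}")
    if not np.allclose(aff1, aff2, atol=1e-4):
        raise ValueError("T1 and T2 affines differ; channels must be co-registered")
    spacing = tuple(np.sqrt((aff1[:3, :3] ** 2).sum(axis=0)))
    return VolumePair(np.stack([t1, t2]), spacing, aff1)


def save_volume_pair(vp: VolumePair, t1_path, t2_path) -> None:
    write_nifti(t1_path, vp.data[0], vp.affine)
    write_nifti(t2_path, vp.data[1], vp.affine)


def load_label_map(path) -> LabelMap:
    arr, aff = read_nifti(path)
    spacing = tuple(np.sqrt((aff[:3, :3] ** 2).sum(axis=0)))
    return LabelMap(np.rint(arr).astype(np.int32), spacing, aff)


def save_label_map(lm: LabelMap, path) -> None:
    write_nifti(path, lm.data.astype(np.int16), lm.affine)
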