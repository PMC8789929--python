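"""In-scope preprocessing: cropping, intensity normalization, and the
standard-resolution simulation, plus declared hooks for the external
denoise / bias-correction / template-registration stages.

The heavy geometric preprocessing of real scans (spatially adaptive
non-local-means denoising, N4 bias correction, affine registration to the
MNI152 template) is delegated to external command-line tools configured as
command templates; phantoms bypass those steps entirely. Everything here
assumes volumes already live on a common template grid.

Voxel coordinates are 0-based with half-open intervals throughout.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import LabelMap, VolumePair

logger = logging.getLogger(__name__)

__all__ = [
    "CropBox",
    "zscore_normalize",
    "crop",
    "paste_back",
    "downsample_upsample",
    "ExternalStep",
    "run_external_steps",
]

_CANONICAL_ORDER = ("denoise", "bias", "register")


class DegenerateInputError(ValueError):
    pass


@dataclass
class CropBox:
    """Per-axis [start, end) voxel intervals in template space."""

    x: tuple
    y: tuple
    z: tuple
    side: str = "right"

    def __post_init__(self):
        for lo, hi in (self.x, self.y, self.z):
            if hi <= lo:
                raise ValueError("crop intervals must be nonempty")

    @property
    def slices(self):
        return tuple(slice(lo, hi) for lo, hi in (self.x, self.y, self.z))

    @property
    def starts(self):
        return (self.x[0], self.y[0], self.z[0])

    @property
    def shape(self):
        return tuple(hi - lo for lo, hi in (self.x, self.y, self.z))

    def padded_to_multiple(self, m: int, bounds: tuple) -> "CropBox":
        """Grow each interval (clamped to `bounds`) until divisible by m."""
        out = []
        for (lo, hi), n in zip((self.x, self.y, self.z), bounds):
            size = hi - lo
            target = -(-size // m) * m
            if target > n:
                raise ValueError(f"cannot pad interval ({lo},{hi}) to multiple of {m}")
            lo2 = max(0, lo - (target - size) // 2)
            hi2 = lo2 + target
            if hi2 > n:
                hi2, lo2 = n, n - target
            out.append((lo2, hi2))
        return CropBox(*out, side=self.side)


def zscore_normalize(x: np.ndarray) -> np.ndarray:
    """Subtract the mean and divide by the standard deviation."""
    x = np.asarray(x, dtype=np.float64)
    sd = x.std()
    if sd == 0:
        raise DegenerateInputError("zero intensity variance; cannot normalize")
    return (x - x.mean()) / sd


def _shift_affine(affine: np.ndarray, starts) -> np.ndarray:
    out = affine.copy()
    out[:3, 3] = affine[:3, 3] + affine[:3, :3] @ np.asarray(starts, dtype=np.float64)
    return out


def crop(x: VolumePair | LabelMap, box: CropBox):
    """Extract the sub-volume; spacing preserved, origin updated so the
    crop is invertible via :func:`paste_back`."""
    shape = x.shape
    for (lo, hi), n in zip((box.x, box.y, box.z), shape):
        if lo < 0 or hi > n:
            raise IndexError(f"crop box ({lo},{hi}) outside volume of size {n}")
    aff = _shift_affine(x.affine, box.starts)
    if isinstance(x, VolumePair):
        return VolumePair(x.data[(slice(None),) + box.slices].copy(), tuple(x.spacing), aff)
    return LabelMap(x.data[box.slices].copy(), tuple(x.spacing), aff)


def paste_back(original, cropped, box: CropBox):
    """Write the cropped voxels back into a copy of the original volume."""
    out = original.copy()
    if isinstance(original, VolumePair):
        out.data[(slice(None),) + box.slices] = cropped.data
    else:
        out.data[box.slices] = cropped.data
    return out


def downsample_upsample(x: np.ndarray, factor: int = 2, method: str = "bspline") -> np.ndarray:
    """Simulate standard-resolution input: resample a channel down by
    `factor` and back up to the original grid with cubic B-spline
    interpolation (mirror boundary)."""
    if method != "bspline":
        raise ValueError(f"unknown resampling method {method!r}")
    factor = int(factor)
    if factor < 2:
        raise ValueError("factor must be an integer >= 2")
    x = np.asarray(x, dtype=np.float64)
    down = ndimage.zoom(x, 1.0 / factor, order=3, mode="mirror", grid_mode=True)
    up = ndimage.zoom(down, [n / m for n, m in zip(x.shape, down.shape)],
                      order=3, mode="mirror", grid_mode=True)
    if up.shape != x.shape:  # guard against rounding in zoom's output shape
        up = up[tuple(slice(0, n) for n in x.shape)]
    return up


@dataclass
class ExternalStep:
    """One external preprocessing command, e.g.
    ``ExternalStep("denoise", "sanlm {input} {output}")``."""

    name: str
    command: str
    enabled: bool = True


def run_external_steps(paths: dict, steps: list) -> tuple[dict, list]:
    """Run the configured external commands in order on each input path.

    `paths` maps channel names to file paths; each enabled step's command
    template is formatted with ``{input}``/``{output}`` per channel and run
    through the shell. Returns (updated paths, provenance records). With
    every step disabled this is the identity. A warning is logged when the
    configured order deviates from denoise -> bias -> register.
    """
    enabled = [s for s in steps if s.enabled]
    canonical = [s for s in enabled if s.name in _CANONICAL_ORDER]
    want = sorted(canonical, key=lambda s: _CANONICAL_ORDER.index(s.name))
    if [s.name for s in canonical] != [s.name for s in want]:
        logger.warning(
            "external steps %s deviate from the canonical order %s",
            [s.name for s in canonical], list(_CANONICAL_ORDER),
        )
    provenance = []
    current = dict(paths)
    for step in enabled:
        exe = step.command.split()[0]
        if shutil.which(exe) is None:
            raise EnvironmentError(
                f"external step {step.name!r} needs executable {exe!r}, not found on PATH"
            )
        for key, inp in list(current.items()):
            outp = f"{inp}.{step.name}"
            cmd = step.command.format(input=inp, output=outp)
            subprocess.run(cmd, shell=True, check=True)
            current[key] = outp
            provenance.append({"step": step.name, "channel": key, "command": cmd})
    return current, provenance
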