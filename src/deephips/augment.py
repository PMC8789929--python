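"""Training-time data augmentation: left-right flip pooling, random
smooth/sharpen, and mixup.

Flip pooling converts every left-side crop into a right-oriented crop by
mirroring along the left-right axis (images and labels identically), so a
bilateral dataset trains a single right-oriented network on twice the
crops. Smoothing/sharpening emulates acquisitions of varying quality;
mixup forms convex combinations of sample pairs with a symmetric
Beta(alpha, alpha) coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import LR_AXIS, LabelMap, VolumePair

__all__ = ["AugmentConfig", "flip_pool", "smooth_sharpen", "mixup"]


@dataclass
class AugmentConfig:
    mixup_alpha: float = 0.3
    smooth_sigma_range: tuple = (0.3, 1.2)  # voxels
    sharpen_amount_range: tuple = (0.2, 1.0)
    apply_probability: float = 0.5  # per-sample chance of each augmentation
    rng_seed: int = 0

    def __post_init__(self):
        if self.mixup_alpha <= 0:
            raise ValueError("mixup_alpha must be > 0")
        for lo, hi in (self.smooth_sigma_range, self.sharpen_amount_range):
            if hi < lo:
                raise ValueError("augmentation ranges must be nonempty")


def flip_pool(samples):
    """Pool bilateral crops into right-oriented ones.

    `samples` is a list of (VolumePair, LabelMap, side) with side in
    {"left", "right"}; left crops are mirrored along the left-right axis,
    right crops pass through. Output count equals input count.
    """
    out = []
    for vp, lm, side in samples:
        if side == "right":
            out.append((vp, lm))
        elif side == "left":
            fvp = VolumePair(
                np.flip(vp.data, axis=1 + LR_AXIS).copy(), tuple(vp.spacing), vp.affine.copy()
            )
            flm = LabelMap(
                np.flip(lm.data, axis=LR_AXIS).copy(), tuple(lm.spacing), lm.affine.copy()
            )
            out.append((fvp, flm))
        else:
            raise ValueError(f"unknown side tag {side!r}")
    return out


def smooth_sharpen(x: VolumePair, cfg: AugmentConfig, rng: np.random.Generator) -> VolumePair:
    """With equal probability smooth (Gaussian, sigma drawn from
    `smooth_sigma_range`) or sharpen (unsharp masking, amount drawn from
    `sharpen_amount_range`) both channels identically; labels untouched."""
    out = x.copy()
    if rng.random() < 0.5:
        sigma = rng.uniform(*cfg.smooth_sigma_range)
        if sigma > 0:
            for c in range(out.data.shape[0]):
                out.data[c] = ndimage.gaussian_filter(out.data[c], sigma)
    else:
        amount = rng.uniform(*cfg.sharpen_amount_range)
        for c in range(out.data.shape[0]):
            blurred = ndimage.gaussian_filter(out.data[c], 1.0)
            out.data[c] = out.data[c] + amount * (out.data[c] - blurred)
    return out


def mixup(a, b, alpha: float = 0.3, rng: np.random.Generator | None = None):
    """Convex combination of two (VolumePair, label-field) samples.

    Label fields are one-hot or soft ``(NC, X, Y, Z)`` arrays; the output
    label rows still sum to one. Returns ``(VolumePair, soft label field)``.
    """
    (xa, ya), (xb, yb) = a, b
    if xa.data.shape != xb.data.shape or np.shape(ya) != np.shape(yb):
        raise ValueError("mixup inputs must share the same grid")
    rng = rng or np.random.default_rng(0)
    lam = rng.beta(alpha, alpha)
    data = lam * xa.data + (1 - lam) * xb.data
    labels = lam * np.asarray(ya, dtype=np.float64) + (1 - lam) * np.asarray(yb, dtype=np.float64)
    return VolumePair(data, tuple(xa.spacing), xa.affine.copy()), labels
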