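"""Region-overlap training objectives for multi-class segmentation.

Implements the five objectives compared when selecting the training loss:
categorical cross-entropy (CCE), Dice loss (DL), generalized Dice loss
(GDL), Jaccard loss (JL), and the generalized Jaccard loss (GJL) in which
class weights are the *inverse volume* ``w_c = 1/V_c`` rather than GDL's
inverse squared volume — the squared weighting is known to destabilize
training when a class is small or absent, which the linear weighting
mitigates.

All functions accept either plain numpy arrays or autodiff
:class:`~deephips.autodiff.Tensor` predictions (gradients flow through the
prediction only; the target is always treated as a constant). Arrays are
class-first ``(NC, ...)`` by default; pass ``class_axis=-1`` for row-wise
``(N, NC)`` matrices.

A smoothing constant ``eps = 1e-5`` is added to every ratio denominator so
absent classes can never produce a division by zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor

logger = logging.getLogger(__name__)

EPS_SMOOTH = 1e-5  # denominator smoothing for the overlap ratios
EPS_PROB = 1e-7  # probability clipping before logarithms

__all__ = [
    "ClassWeights",
    "MultiscaleLossWeights",
    "dice_loss",
    "generalized_dice_loss",
    "jaccard_loss",
    "generalized_jaccard_loss",
    "categorical_cross_entropy",
    "class_weights",
    "multiscale_loss",
    "get_loss",
]


def _canon(x, class_axis):
    """Move the class axis first and flatten voxels: -> (NC, N)."""
    if isinstance(x, Tensor):
        ax = class_axis % x.ndim
        order = (ax,) + tuple(i for i in range(x.ndim) if i != ax)
        return x.transpose(*order).reshape(x.shape[ax], -1)
    x = np.asarray(x, dtype=np.float64)
    return np.moveaxis(x, class_axis, 0).reshape(x.shape[class_axis], -1)


def _check_shapes(p, t, class_axis):
    ps = p.shape if isinstance(p, Tensor) else np.shape(p)
    ts = t.shape if isinstance(t, Tensor) else np.shape(t)
    if ps != ts:
        raise ValueError(f"prediction/target shape mismatch: {ps} vs {ts}")
    nc = ps[class_axis]
    if nc < 1:
        raise ValueError("need at least one class")
    return nc


def _target_array(t, class_axis) -> np.ndarray:
    t = t.data if isinstance(t, Tensor) else np.asarray(t, dtype=np.float64)
    return np.moveaxis(t, class_axis, 0).reshape(t.shape[class_axis], -1)


@dataclass
class ClassWeights:
    """Per-class nonnegative weights plus the scheme that produced them."""

    w: np.ndarray
    scheme: str
    absent: np.ndarray = field(default=None)

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.absent is None:
            self.absent = np.zeros(self.w.shape, dtype=bool)
        if np.any(self.w < 0) or not np.all(np.isfinite(self.w)):
            raise ValueError("class weights must be finite and nonnegative")


@dataclass
class MultiscaleLossWeights:
    """Weights for the low/medium/high resolution supervision outputs."""

    low: float = 0.1
    medium: float = 0.2
    high: float = 0.7

    def __post_init__(self):
        if min(self.low, self.medium, self.high) < 0:
            raise ValueError("multiscale loss weights must be nonnegative")


def class_weights(t, scheme: str = "inverse-volume", class_axis: int = 0) -> ClassWeights:
    """Compute per-class weights from a one-hot (or soft) target field.

    Schemes: ``quadratic-inverse-volume`` (1/V^2, the GDL convention),
    ``inverse-volume`` (1/V, the GJL convention), ``uniform``. Classes with
    zero volume get weight 0 and are flagged absent.
    """
    tm = _target_array(t, class_axis)
    vols = tm.sum(axis=1)
    absent = vols == 0
    if scheme == "uniform":
        w = np.ones_like(vols)
    elif scheme == "inverse-volume":
        w = np.where(absent, 0.0, 1.0 / np.where(absent, 1.0, vols))
    elif scheme == "quadratic-inverse-volume":
        w = np.where(absent, 0.0, 1.0 / np.where(absent, 1.0, vols) ** 2)
    else:
        raise ValueError(f"unknown class-weight scheme: {scheme!r}")
    w = np.where(absent, 0.0, w)
    if absent.any():
        logger.warning(
            "classes %s have zero volume; their weight is set to 0",
            np.nonzero(absent)[0].tolist(),
        )
    return ClassWeights(w, scheme, absent)


def dice_loss(p, t, class_axis: int = 0):
    """Soft Dice loss, averaged per class.

    ``1 - (2/NC) * sum_c [ sum_i p*t / (sum_i p + t + eps) ]``
    """
    nc = _check_shapes(p, t, class_axis)
    pm = _canon(p, class_axis)
    tm = _target_array(t, class_axis)
    inter = (pm * tm).sum(axis=1)
    denom = pm.sum(axis=1) + tm.sum(axis=1) + EPS_SMOOTH
    return 1.0 - (2.0 / nc) * (inter / denom).sum()


def generalized_dice_loss(p, t, class_axis: int = 0):
    """Generalized Dice loss with quadratic inverse-volume class weights,
    pooled over classes before the ratio."""
    _check_shapes(p, t, class_axis)
    pm = _canon(p, class_axis)
    tm = _target_array(t, class_axis)
    w = class_weights(t, "quadratic-inverse-volume", class_axis).w
    inter = ((pm * tm).sum(axis=1) * w).sum()
    denom = ((pm.sum(axis=1) + tm.sum(axis=1)) * w).sum() + EPS_SMOOTH
    return 1.0 - 2.0 * inter / denom


def jaccard_loss(p, t, class_axis: int = 0, literal: bool = False):
    """Soft Jaccard loss.

    By default the per-class-mean form
    ``1 - (1/NC) * sum_c inter_c / union_c`` is used, which vanishes at
    perfect overlap like the Dice loss. ``literal=True`` selects the variant
    that places ``1/NC`` outside a single pooled ratio; that form evaluates
    to ``1 - 1/NC`` even on a perfect prediction and is provided for
    comparison only.
    """
    nc = _check_shapes(p, t, class_axis)
    pm = _canon(p, class_axis)
    tm = _target_array(t, class_axis)
    inter = (pm * tm).sum(axis=1)
    union = pm.sum(axis=1) + tm.sum(axis=1) - inter
    if literal:
        return 1.0 - (1.0 / nc) * inter.sum() / (union.sum() + EPS_SMOOTH)
    return 1.0 - (1.0 / nc) * (inter / (union + EPS_SMOOTH)).sum()


def generalized_jaccard_loss(p, t, class_axis: int = 0):
    """Generalized Jaccard loss: pooled Jaccard with inverse-volume weights.

    ``1 - sum_c w_c inter_c / (sum_c w_c union_c)`` with ``w_c = 1/V_c``.
    With uniform weights this reduces to the pooled Jaccard loss.
    """
    _check_shapes(p, t, class_axis)
    pm = _canon(p, class_axis)
    tm = _target_array(t, class_axis)
    w = class_weights(t, "inverse-volume", class_axis).w
    inter = (pm * tm).sum(axis=1)
    union = pm.sum(axis=1) + tm.sum(axis=1) - inter
    return 1.0 - (inter * w).sum() / ((union * w).sum() + EPS_SMOOTH)


def categorical_cross_entropy(p, t, class_axis: int = 0):
    """Mean over voxels of ``-sum_c t log p``, with p clipped to
    ``[1e-7, 1 - 1e-7]`` before the logarithm."""
    _check_shapes(p, t, class_axis)
    pm = _canon(p, class_axis)
    tm = _target_array(t, class_axis)
    n_vox = tm.shape[1]
    pc = pm.clip(EPS_PROB, 1.0 - EPS_PROB)
    logp = pc.log() if isinstance(pc, Tensor) else np.log(pc)
    return -(tm * logp).sum() * (1.0 / n_vox)


def multiscale_loss(losses_per_scale, w: MultiscaleLossWeights | None = None):
    """Weighted sum of the (low, medium, high) resolution losses."""
    if w is None:
        w = MultiscaleLossWeights()
    low, medium, high = losses_per_scale
    return w.low * low + w.medium * medium + w.high * high


_REGISTRY = {
    "cce": categorical_cross_entropy,
    "dl": dice_loss,
    "gdl": generalized_dice_loss,
    "jl": jaccard_loss,
    "gjl": generalized_jaccard_loss,
}


def get_loss(name: str):
    """Look up a loss by its config name (cce|dl|gdl|jl|gjl)."""
    try:
        return _REGISTRY[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown loss {name!r}; choose from {sorted(_REGISTRY)}"
        ) from None
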