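"""Prediction engines: standard evaluation-mode prediction and
training-time batch normalization (TTBN).

Standard prediction runs normalization layers with their stored running
statistics. TTBN instead recomputes the normalization statistics from the
presented sample at every call — the running averages accumulated during
training with batch size one are often poor summaries of an individual
test case, especially under intensity domain shift, and per-sample
statistics remove that mismatch. In both modes stochastic layers
(dropout) are disabled and the model state is left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LabelMap, VolumePair
from .network import ConfigurationError, DSUNet3D

__all__ = ["PredictionConfig", "predict"]


@dataclass
class PredictionConfig:
    mode: str = "standard"  # "standard" | "ttbn"
    argmax: bool = False  # emit a LabelMap instead of probabilities

    def __post_init__(self):
        if self.mode not in ("standard", "ttbn"):
            raise ValueError(f"unknown prediction mode {self.mode!r}")


def predict(g: DSUNet3D, x: VolumePair, cfg: PredictionConfig | None = None):
    """Segment one volume pair.

    Returns the full-resolution probability field ``(NC, X, Y, Z)``, or a
    :class:`LabelMap` of per-voxel most-probable classes if ``cfg.argmax``.
    """
    cfg = cfg or PredictionConfig()
    if cfg.mode == "ttbn" and not g.has_batchnorm():
        raise ConfigurationError(
            "TTBN prediction requires normalization layers in the graph"
        )
    mode = "ttbn" if cfg.mode == "ttbn" else "eval"
    probs = g.forward(x, mode=mode)["high"].data
    if not cfg.argmax:
        return probs
    labels = np.argmax(probs, axis=0).astype(np.int32)
    if isinstance(x, VolumePair):
        return LabelMap(labels, tuple(x.spacing), x.affine.copy())
    return LabelMap(labels)
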