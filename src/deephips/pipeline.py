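"""End-to-end training and cross-validation orchestration.

Training follows the experimental protocol: Adam with default parameters,
batch size one, a configurable overlap loss applied at all three
supervision scales with multiscale weights (0.1, 0.2, 0.7) for the
low/medium/high resolution outputs, and the best-validation-loss
checkpoint retained. Ground truth for the coarse supervision scales is
obtained by majority-vote downsampling of the one-hot labels, which keeps
the targets valid one-hot fields and never invents labels.

All randomness (shuffling, dropout, augmentation) derives from the single
configured seed, so two runs with the same seed produce identical loss
histories.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from . import augment as aug
from .autodiff import Tensor
from .core import LabelMap, VolumePair, one_hot
from .evaluate import FoldPlan, dice_report, make_folds, summarize_reports
from .inference import PredictionConfig, predict
from .losses import MultiscaleLossWeights, get_loss, multiscale_loss
from .network import DSUNet3D, NetworkSpec, build_ds_unet3d

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "TrainingDiverged",
    "Adam",
    "downsample_labels_majority",
    "train",
    "run_crossval",
    "run_ablation",
]


class TrainingDiverged(RuntimeError):
    pass


class Adam:
    """Adam optimizer with the standard default parameters."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


@dataclass
class TrainingConfig:
    loss: str = "gjl"
    epochs: int = 200
    batch_size: int = 1
    learning_rate: float = 1e-3
    multiscale_weights: MultiscaleLossWeights = field(default_factory=MultiscaleLossWeights)
    augment: aug.AugmentConfig | None = None
    seed: int = 0
    max_steps: int | None = None  # optional hard cap on optimizer steps
    jl_literal: bool = False

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


def downsample_labels_majority(labels: np.ndarray, factor: int) -> np.ndarray:
    """Majority-vote downsampling of an integer label volume.

    Ties break toward the lowest label index. The output vocabulary is a
    subset of the input's; a structure thicker than the coarse voxel is
    never lost.
    """
    labels = np.asarray(labels)
    f = int(factor)
    if f == 1:
        return labels.copy()
    X, Y, Z = labels.shape
    if X % f or Y % f or Z % f:
        raise ValueError(f"shape {labels.shape} not divisible by factor {f}")
    blocks = labels.reshape(X // f, f, Y // f, f, Z // f, f)
    blocks = blocks.transpose(0, 2, 4, 1, 3, 5).reshape(X // f, Y // f, Z // f, -1)
    n_classes = int(labels.max()) + 1
    counts = np.stack([(blocks == c).sum(axis=-1) for c in range(n_classes)], axis=0)
    return np.argmax(counts, axis=0).astype(labels.dtype)


def _scale_targets(lm: LabelMap, n_classes: int, levels: int) -> dict:
    """One-hot targets for the high/medium/low supervision outputs."""
    lab = lm.data
    return {
        "high": one_hot(lab, n_classes),
        "medium": one_hot(downsample_labels_majority(lab, 2 ** (levels - 2)), n_classes),
        "low": one_hot(downsample_labels_majority(lab, 2 ** (levels - 1)), n_classes),
    }


def _sample_loss(model: DSUNet3D, vp: VolumePair, target, cfg: TrainingConfig,
                 mode: str, rng) -> Tensor | float:
    """Forward pass plus the (possibly multiscale) training objective.

    `target` is a LabelMap or an already one-hot/soft (NC, X, Y, Z) array
    (soft labels arise from mixup)."""
    spec = model.spec
    loss_fn = get_loss(cfg.loss)
    kwargs = {"literal": True} if (cfg.loss == "jl" and cfg.jl_literal) else {}
    outputs = model.forward(vp, mode=mode, rng=rng)
    if isinstance(target, LabelMap):
        if spec.deep_supervision:
            targets = _scale_targets(target, spec.n_classes, spec.levels)
        else:
            targets = {"high": one_hot(target.data, spec.n_classes)}
    else:
        target = np.asarray(target, dtype=np.float64)
        targets = {"high": target}
        if spec.deep_supervision:
            # soft targets: average-pool to the coarse scales
            for name, k in (("medium", spec.levels - 2), ("low", spec.levels - 1)):
                f = 2**k
                nc = target.shape[0]
                X, Y, Z = target.shape[1:]
                t = target.reshape(nc, X // f, f, Y // f, f, Z // f, f).mean(axis=(2, 4, 6))
                targets[name] = t
    if not spec.deep_supervision:
        return loss_fn(outputs["high"], targets["high"], **kwargs)
    per_scale = tuple(
        loss_fn(outputs[name], targets[name], **kwargs)
        for name in ("low", "medium", "high")
    )
    return multiscale_loss(per_scale, cfg.multiscale_weights)


def train(spec: NetworkSpec, data, cfg: TrainingConfig, val_data=None,
          model: DSUNet3D | None = None):
    """Train a DS-UNET3D on (VolumePair, LabelMap) samples.

    Returns ``(model, history)``; `history` has one entry per epoch with
    training and validation loss, and the model ends loaded with the
    best-validation checkpoint (best training loss if no validation data).
    """
    data = list(data)
    val_data = list(val_data) if val_data else []
    rng = np.random.default_rng(cfg.seed)
    if model is None:
        model = build_ds_unet3d(spec)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    aug_cfg = cfg.augment
    history = []
    best = (np.inf, None)
    steps = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(data))
        epoch_losses = []
        for idx in order:
            vp, target = data[idx]
            if aug_cfg is not None:
                vp, target = _augment_sample(vp, target, data, aug_cfg,
                                             model.spec.n_classes, rng)
            opt.zero_grad()
            loss = _sample_loss(model, vp, target, cfg, "train", rng)
            value = float(loss.data)
            if not np.isfinite(value):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, sample index {int(idx)}"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(value)
            steps += 1
            if cfg.max_steps is not None and steps >= cfg.max_steps:
                break
        entry = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if val_data:
            vls = [
                float(_sample_loss(model, vp, t, cfg, "eval", None).data)
                for vp, t in val_data
            ]
            entry["val_loss"] = float(np.mean(vls))
            score = entry["val_loss"]
        else:
            score = entry["train_loss"]
        history.append(entry)
        if score < best[0]:
            best = (score, model.get_state())
        logger.debug("epoch %d: %s", epoch, entry)
        if cfg.max_steps is not None and steps >= cfg.max_steps:
            break
    if best[1] is not None:
        model.set_state(best[1])
    return model, history


def _augment_sample(vp, target, data, aug_cfg, n_classes, rng):
    """Apply the configured augmentations to one training sample."""
    if rng.random() < aug_cfg.apply_probability:
        vp = aug.smooth_sharpen(vp, aug_cfg, rng)
    if rng.random() < aug_cfg.apply_probability and len(data) > 1:
        j = int(rng.integers(len(data)))
        vp_b, t_b = data[j]
        ya = (one_hot(target.data, n_classes) if isinstance(target, LabelMap)
              else np.asarray(target))
        yb = (one_hot(t_b.data, n_classes) if isinstance(t_b, LabelMap)
              else np.asarray(t_b))
        vp, target = aug.mixup((vp, ya), (vp_b, yb), aug_cfg.mixup_alpha, rng)
    return vp, target


def run_crossval(dataset: dict, spec: NetworkSpec, cfg: TrainingConfig,
                 K: int = 5, plan: FoldPlan | None = None,
                 modes=("standard",), predictor=None,
                 test_transform=None):
    """K-fold cross-validation over a dataset of id -> (VolumePair, LabelMap).

    Trains one model per fold (unless a `predictor` callable overrides
    prediction entirely), evaluates every sample exactly once in its test
    fold under each prediction mode, and returns
    ``(per-sample reports, pooled summary DataFrame, plan)``.

    `test_transform` optionally corrupts test inputs (e.g. an intensity
    shift) to probe robustness of the prediction modes.
    """
    ids = sorted(dataset)
    if plan is None:
        plan = make_folds(ids, K, cfg.seed)
    for fold in plan.folds:
        if not fold["test"]:
            raise ValueError("fold with empty test set")
    reports = {}
    for fold_idx, fold in enumerate(plan.folds):
        if predictor is None:
            train_samples = [dataset[i] for i in fold["train"]]
            val_samples = [dataset[i] for i in fold["val"]]
            fold_cfg = dataclasses.replace(cfg, seed=cfg.seed + fold_idx)
            model, _ = train(spec, train_samples, fold_cfg, val_samples)
        for sid in fold["test"]:
            vp, truth = dataset[sid]
            if test_transform is not None:
                vp = test_transform(vp)
            per_mode = {}
            for mode in modes:
                if predictor is not None:
                    pred = predictor(vp)
                else:
                    pred = predict(model, vp, PredictionConfig(mode=mode, argmax=True))
                per_mode[mode] = dice_report(pred, truth)
            reports[sid] = per_mode
    summary = summarize_reports(reports)
    return reports, summary, plan


def run_ablation(dataset: dict, specs: dict, cfg: TrainingConfig, K: int = 5,
                 modes=("standard",)):
    """Train each named architecture on identical folds and pool their
    summaries side by side (e.g. deep-supervised vs classic U-Net)."""
    import pandas as pd

    ids = sorted(dataset)
    plan = make_folds(ids, K, cfg.seed)
    summaries = {}
    for name, spec in specs.items():
        _, summary, _ = run_crossval(dataset, spec, cfg, K=K, plan=plan, modes=modes)
        summaries[name] = summary
    return pd.concat(summaries, axis=1), plan
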