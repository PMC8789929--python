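"""Dice-based evaluation and the K-fold experimental harness.

Accuracy is reported as the Dice coefficient per structure, the unweighted
mean over structures (background excluded), and the whole-structure Dice
of the union of all non-background labels, matching the usual presentation
for subfield protocols. Empty-versus-empty masks score Dice 1 (both raters
agree the structure is absent); empty versus non-empty scores 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LabelMap

__all__ = ["FoldPlan", "DiceReport", "dice", "dice_report", "make_folds", "summarize_reports"]


def _mask_arrays(a, b):
    a = a.data if isinstance(a, LabelMap) else np.asarray(a)
    b = b.data if isinstance(b, LabelMap) else np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"label grids differ: {a.shape} vs {b.shape}")
    return a, b


def dice(a, b, label: int) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) of the binary masks of `label`."""
    a, b = _mask_arrays(a, b)
    ma, mb = a == label, b == label
    na, nb = int(ma.sum()), int(mb.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int(np.logical_and(ma, mb).sum()) / (na + nb)


@dataclass
class DiceReport:
    """Per-structure Dice, their unweighted average, and whole-structure
    (union of all non-background labels) Dice."""

    per_structure: dict
    average: float
    whole: float

    def as_dict(self) -> dict:
        out = {f"label_{k}": v for k, v in self.per_structure.items()}
        out["average"] = self.average
        out["whole"] = self.whole
        return out


def dice_report(pred, truth, labels=None) -> DiceReport:
    """Evaluate a predicted label map against the reference.

    `labels` defaults to every non-background label present in either map.
    """
    pa, ta = _mask_arrays(pred, truth)
    if labels is None:
        labels = sorted(set(np.unique(pa)) | set(np.unique(ta)))
        labels = [int(l) for l in labels if l != 0]
    per = {int(l): dice(pa, ta, l) for l in labels}
    avg = float(np.mean(list(per.values()))) if per else 1.0
    whole_p, whole_t = (pa > 0).astype(np.int8), (ta > 0).astype(np.int8)
    return DiceReport(per, avg, dice(whole_p, whole_t, 1))


@dataclass
class FoldPlan:
    """Deterministic K-fold partition with a per-fold validation subset."""

    K: int
    seed: int
    folds: list  # of {"train": [...], "val": [...], "test": [...]}

    def all_test_ids(self):
        out = []
        for f in self.folds:
            out.extend(f["test"])
        return out

    def to_json(self, path=None) -> str:
        text = json.dumps({"K": self.K, "seed": self.seed, "folds": self.folds}, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FoldPlan":
        data = json.loads(source if isinstance(source, str) and source.lstrip().startswith("{")
                          else open(source).read())
        return cls(data["K"], data["seed"], data["folds"])


def make_folds(sample_ids, K: int, seed: int, n_val: int | None = None) -> FoldPlan:
    """Seeded shuffle followed by a contiguous K-way partition.

    Each fold tests one chunk and trains on the rest; the last `n_val`
    entries of the shuffled training list are held out for validation.
    The default ``n_val = max(2, round(n_train / 8))`` gives 5 validation
    cases for 40 training crops and 2 for 8.
    """
    sample_ids = list(sample_ids)
    if K < 2 or K > len(sample_ids):
        raise ValueError(f"K={K} incompatible with {len(sample_ids)} samples")
    rng = np.random.default_rng(seed)
    order = [sample_ids[i] for i in rng.permutation(len(sample_ids))]
    chunks = [list(c) for c in np.array_split(np.arange(len(order)), K)]
    folds = []
    for k in range(K):
        test = [order[i] for i in chunks[k]]
        train_full = [order[i] for c in range(K) if c != k for i in chunks[c]]
        nv = n_val if n_val is not None else max(2, round(len(train_full) / 8))
        if nv >= len(train_full):
            raise ValueError("validation subset would consume the whole training set")
        folds.append({
            "train": train_full[:-nv],
            "val": train_full[-nv:],
            "test": test,
        })
    return FoldPlan(K, seed, folds)


def summarize_reports(reports: dict) -> pd.DataFrame:
    """Aggregate per-sample DiceReports into a mean ± sd table.

    `reports` maps sample id -> DiceReport (or -> {mode: DiceReport} for
    multi-mode comparisons). Rows: each structure, Average, Whole; columns:
    ``mean``/``sd`` per mode.
    """
    first = next(iter(reports.values()))
    modes = list(first) if isinstance(first, dict) else [None]
    frames = {}
    for mode in modes:
        rows = {}
        for sid, rep in reports.items():
            r = rep[mode] if mode is not None else rep
            row = {f"label_{k}": v for k, v in r.per_structure.items()}
            row["Average"] = r.average
            row["Whole"] = r.whole
            rows[sid] = row
        df = pd.DataFrame(rows).T
        stats = pd.DataFrame({"mean": df.mean(axis=0), "sd": df.std(axis=0, ddof=1)})
        frames[mode if mode is not None else "dice"] = stats
    return pd.concat(frames, axis=1)
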