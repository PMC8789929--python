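"""Shared fixtures: random loss instances, small phantoms, and the
session-scoped trained model used by the end-to-end checks."""

from __future__ import annotations

import numpy as np
import pytest

from deephips import NetworkSpec, TrainingConfig
from deephips.phantom import PhantomConfig, generate
from deephips.pipeline import train
from deephips.preprocess import zscore_normalize

# problem sizes chosen so the full suite runs in minutes on one CPU
SMOKE_SHAPE = (32, 24, 32)
SMOKE_GEOMETRY = {"tube_radius": 5.0, "arc_radius": 7.0}


def random_instance(rng, n=None, nc=None):
    """A random (p, t) pair: rows of p on the simplex, t one-hot with every
    class present."""
    n = n or int(rng.integers(4, 101))
    nc = nc or int(rng.integers(2, 6))
    p = rng.dirichlet(np.ones(nc), size=n)
    labels = np.concatenate([np.arange(nc), rng.integers(0, nc, n - nc)])
    rng.shuffle(labels)
    t = np.eye(nc)[labels]
    return p, t


def make_phantom(seed, shape=SMOKE_SHAPE, n_subfields=3, normalized=True, **kw):
    params = dict(SMOKE_GEOMETRY)
    params.update(kw)
    cfg = PhantomConfig(shape=shape, n_subfields=n_subfields, seed=seed, **params)
    vp, lm, side = generate(cfg)
    if normalized:
        for c in range(vp.data.shape[0]):
            vp.data[c] = zscore_normalize(vp.data[c])
    return vp, lm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_spec():
    return NetworkSpec(levels=3, base_filters=8, n_classes=4, init_seed=0)


@pytest.fixture(scope="session")
def smoke_training(tiny_spec):
    """A small deeply supervised network trained with the generalized
    Jaccard loss for 300 optimizer steps on 20 seeded phantoms (15 epochs
    of 20 samples, batch size one). Shared by the learning and TTBN
    robustness checks."""
    train_set = [make_phantom(seed) for seed in range(20)]
    cfg = TrainingConfig(loss="gjl", epochs=15, seed=0)
    model, history = train(tiny_spec, train_set, cfg)
    return model, history
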