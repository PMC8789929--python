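"""Overlap losses against literal voxel-loop oracles and their invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deephips import losses as L
from conftest import random_instance

# ---------------------------------------------------------------------------
# literal double-loop (voxel x class) oracle implementations
# ---------------------------------------------------------------------------


def oracle_dice(p, t):
    n, nc = p.shape
    acc = 0.0
    for c in range(nc):
        inter = sum(p[i, c] * t[i, c] for i in range(n))
        denom = sum(p[i, c] + t[i, c] for i in range(n)) + L.EPS_SMOOTH
        acc += inter / denom
    return 1.0 - (2.0 / nc) * acc


def oracle_gdl(p, t):
    n, nc = p.shape
    num = den = 0.0
    for c in range(nc):
        v = sum(t[i, c] for i in range(n))
        w = 0.0 if v == 0 else 1.0 / v**2
        num += w * sum(p[i, c] * t[i, c] for i in range(n))
        den += w * sum(p[i, c] + t[i, c] for i in range(n))
    return 1.0 - 2.0 * num / (den + L.EPS_SMOOTH)


def oracle_jl(p, t):
    n, nc = p.shape
    acc = 0.0
    for c in range(nc):
        inter = sum(p[i, c] * t[i, c] for i in range(n))
        union = sum(p[i, c] + t[i, c] for i in range(n)) - inter
        acc += inter / (union + L.EPS_SMOOTH)
    return 1.0 - acc / nc


def oracle_gjl(p, t):
    n, nc = p.shape
    num = den = 0.0
    for c in range(nc):
        v = sum(t[i, c] for i in range(n))
        w = 0.0 if v == 0 else 1.0 / v
        inter = sum(p[i, c] * t[i, c] for i in range(n))
        union = sum(p[i, c] + t[i, c] for i in range(n)) - inter
        num += w * inter
        den += w * union
    return 1.0 - num / (den + L.EPS_SMOOTH)


def oracle_cce(p, t):
    n, nc = p.shape
    total = 0.0
    for i in range(n):
        for c in range(nc):
            total -= t[i, c] * np.log(np.clip(p[i, c], L.EPS_PROB, 1 - L.EPS_PROB))
    return total / n


ORACLES = {
    "dl": (L.dice_loss, oracle_dice),
    "gdl": (L.generalized_dice_loss, oracle_gdl),
    "jl": (L.jaccard_loss, oracle_jl),
    "gjl": (L.generalized_jaccard_loss, oracle_gjl),
    "cce": (L.categorical_cross_entropy, oracle_cce),
}

# the worked 2-voxel, 2-class instance used throughout
P2 = np.array([[0.8, 0.2], [0.4, 0.6]])
T2 = np.array([[1.0, 0.0], [0.0, 1.0]])


class TestFrozenValues:
    """Hand-derived values on the 2x2 instance (volumes (1,1), w=(1,1))."""

    @pytest.mark.parametrize(
        "fn,expected",
        [
            (L.dice_loss, 1 - (0.8 / 2.2 + 0.6 / 1.8)),  # 0.30303
            (L.generalized_dice_loss, 1 - 2 * (0.8 + 0.6) / (2.2 + 1.8)),  # 0.3
            (L.jaccard_loss, 1 - 0.5 * (0.8 / 1.4 + 0.6 / 1.2)),  # 0.46429
            (L.generalized_jaccard_loss, 1 - 1.4 / (1.4 + 1.2)),  # 0.46154
            (L.categorical_cross_entropy, -(np.log(0.8) + np.log(0.6)) / 2),  # 0.36696
        ],
    )
    def test_two_voxel_instance(self, fn, expected):
        assert fn(P2, T2, class_axis=-1) == pytest.approx(expected, abs=1e-4)

    def test_uniform_prediction_cce_is_log_nc(self, rng):
        nc = 4
        p = np.full((50, nc), 1.0 / nc)
        t = np.eye(nc)[rng.integers(0, nc, 50)]
        assert L.categorical_cross_entropy(p, t, class_axis=-1) == pytest.approx(
            np.log(nc), rel=1e-9
        )

    def test_literal_jaccard_cannot_vanish_at_perfect_overlap(self, rng):
        # the pooled-ratio form evaluates to 1 - 1/NC on a perfect prediction,
        # which motivates the per-class-mean default
        for nc in (2, 3, 5):
            _, t = random_instance(rng, n=30, nc=nc)
            val = L.jaccard_loss(t, t, class_axis=-1, literal=True)
            assert val == pytest.approx(1 - 1 / nc, abs=1e-4)
            assert L.jaccard_loss(t, t, class_axis=-1) == pytest.approx(0, abs=1e-4)


class TestOracleEquivalence:
    @pytest.mark.parametrize("name", sorted(ORACLES))
    def test_matches_voxel_loop(self, name, rng):
        fn, oracle = ORACLES[name]
        for _ in range(30):
            p, t = random_instance(rng)
            assert fn(p, t, class_axis=-1) == pytest.approx(
                oracle(p, t), abs=1e-6
            )


class TestPerfectAndZeroOverlap:
    @pytest.mark.parametrize(
        "fn",
        [L.dice_loss, L.generalized_dice_loss, L.jaccard_loss, L.generalized_jaccard_loss],
    )
    def test_perfect_prediction_gives_zero(self, fn, rng):
        for nc in (2, 3, 5):
            _, t = random_instance(rng, n=40, nc=nc)
            assert fn(t, t, class_axis=-1) == pytest.approx(0.0, abs=1e-4)

    @pytest.mark.parametrize(
        "fn",
        [L.dice_loss, L.generalized_dice_loss, L.jaccard_loss, L.generalized_jaccard_loss],
    )
    def test_total_disagreement_gives_one(self, fn):
        # one-hot prediction disagreeing at every voxel for every class
        t = np.eye(2)[np.array([0, 0, 1, 1])]
        p = np.eye(2)[np.array([1, 1, 0, 0])]
        assert fn(p, t, class_axis=-1) == pytest.approx(1.0, abs=1e-4)

    def test_perfect_cce_bounded_by_clipping(self, rng):
        _, t = random_instance(rng, n=20, nc=3)
        val = L.categorical_cross_entropy(t, t, class_axis=-1)
        assert 0 <= val <= -np.log(1 - L.EPS_PROB) * 3 + 1e-9


class TestInvariances:
    @pytest.mark.parametrize("name", sorted(ORACLES))
    def test_voxel_and_class_permutation(self, name, rng):
        fn, _ = ORACLES[name]
        p, t = random_instance(rng, n=50, nc=4)
        base = fn(p, t, class_axis=-1)
        vperm = rng.permutation(50)
        assert fn(p[vperm], t[vperm], class_axis=-1) == pytest.approx(base, rel=1e-12)
        cperm = rng.permutation(4)
        assert fn(p[:, cperm], t[:, cperm], class_axis=-1) == pytest.approx(
            base, rel=1e-12
        )

    def test_gdl_scale_invariant_in_weights(self, rng):
        # doubling every class volume multiplies all w_c by 1/4; the ratio of
        # homogeneous sums is unchanged, so duplicating the instance (which
        # doubles every volume) preserves GDL
        p, t = random_instance(rng, n=30, nc=3)
        doubled = L.generalized_dice_loss(
            np.vstack([p, p]), np.vstack([t, t]), class_axis=-1
        )
        # agreement is limited only by the eps smoothing term
        assert doubled == pytest.approx(
            L.generalized_dice_loss(p, t, class_axis=-1), abs=1e-4
        )

    def test_equal_volumes_reduce_generalized_to_pooled(self, rng):
        # with equal class volumes the weights cancel: GJL == pooled Jaccard
        # and GDL == pooled Dice
        nc, per = 3, 10
        labels = np.repeat(np.arange(nc), per)
        rng.shuffle(labels)
        t = np.eye(nc)[labels]
        p = rng.dirichlet(np.ones(nc), size=nc * per)
        inter = (p * t).sum(axis=0)
        union = p.sum(axis=0) + t.sum(axis=0) - inter
        pooled_jl = 1 - inter.sum() / union.sum()
        pooled_dl = 1 - 2 * inter.sum() / (p.sum() + t.sum())
        assert L.generalized_jaccard_loss(p, t, class_axis=-1) == pytest.approx(
            pooled_jl, abs=1e-5
        )
        assert L.generalized_dice_loss(p, t, class_axis=-1) == pytest.approx(
            pooled_dl, abs=1e-5
        )

    def test_channel_first_layout_agrees_with_row_layout(self, rng):
        p, t = random_instance(rng, n=24, nc=4)
        pv = p.T.reshape(4, 2, 3, 4)
        tv = t.T.reshape(4, 2, 3, 4)
        for fn, _ in ORACLES.values():
            assert fn(pv, tv) == pytest.approx(fn(p, t, class_axis=-1), rel=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_overlap_losses_bounded(seed):
    """Every overlap loss lies in [0, 1 + O(eps)] on random instances."""
    r = np.random.default_rng(seed)
    p, t = random_instance(r)
    for fn in (
        L.dice_loss,
        L.generalized_dice_loss,
        L.jaccard_loss,
        L.generalized_jaccard_loss,
    ):
        val = fn(p, t, class_axis=-1)
        assert -1e-6 <= val <= 1.0 + 1e-4


class TestClassWeights:
    def test_inverse_volume(self):
        t = np.repeat(np.eye(2), [10, 2], axis=0)
        cw = L.class_weights(t, "inverse-volume", class_axis=-1)
        assert cw.w == pytest.approx([0.1, 0.5])

    def test_quadratic(self):
        t = np.repeat(np.eye(2), [10, 2], axis=0)
        cw = L.class_weights(t, "quadratic-inverse-volume", class_axis=-1)
        assert cw.w == pytest.approx([0.01, 0.25])

    def test_uniform(self):
        t = np.repeat(np.eye(3), [1, 2, 3], axis=0)
        assert L.class_weights(t, "uniform", class_axis=-1).w == pytest.approx([1, 1, 1])

    def test_absent_class_dropped_with_warning(self, caplog):
        t = np.zeros((4, 2))
        t[:, 0] = 1  # class 1 absent
        with caplog.at_level("WARNING"):
            cw = L.class_weights(t, "inverse-volume", class_axis=-1)
        assert cw.w == pytest.approx([0.25, 0.0])
        assert cw.absent.tolist() == [False, True]
        assert any("zero volume" in r.message for r in caplog.records)

    def test_absent_class_never_nan(self):
        t = np.zeros((6, 3))
        t[:, 0] = 1
        p = np.full((6, 3), 1 / 3)
        for fn in (L.generalized_dice_loss, L.generalized_jaccard_loss):
            assert np.isfinite(fn(p, t, class_axis=-1))

    def test_unknown_scheme(self):
        with pytest.raises(ValueError, match="scheme"):
            L.class_weights(np.eye(2), "geometric")


class TestMultiscale:
    def test_defaults_sum_to_one(self):
        assert L.multiscale_loss((1.0, 1.0, 1.0)) == pytest.approx(1.0)

    def test_high_only(self):
        assert L.multiscale_loss((0.0, 0.0, 2.0)) == pytest.approx(1.4)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            L.MultiscaleLossWeights(low=-0.1)

    def test_registry(self):
        assert L.get_loss("GJL") is L.generalized_jaccard_loss
        with pytest.raises(ValueError, match="unknown loss"):
            L.get_loss("tversky")


class TestValidation:
    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            L.dice_loss(np.eye(3), np.eye(4))

    def test_probability_field_helper(self):
        from deephips.core import is_probability_field

        good = np.full((3, 2, 2, 2), 1 / 3)
        assert is_probability_field(good)
        assert not is_probability_field(good * 1.2)
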