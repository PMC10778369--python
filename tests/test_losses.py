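"""Loss functions against independent per-pixel summation oracles."""

import math

import numpy as np
import pytest

from ihcseg.losses import (LossWeights, bas_loss, boundary_bce, supervised_loss,
                           unimatch_loss, weighted_ce)
from ihcseg.network import NetworkOutputs
from ihcseg.nn import Tensor

# oracle comparisons at 1e-6 need double precision throughout
pytestmark = pytest.mark.usefixtures("float64_mode")


def random_probs(rng, c, h, w):
    p = rng.random((c, h, w)) + 1e-3
    return p / p.sum(axis=0, keepdims=True)


# ---------------------------------------------------------------- oracles
def oracle_weighted_ce(probs, gt, weights):
    total = 0.0
    c, h, w = probs.shape
    for r in range(h):
        for col in range(w):
            k = gt[r, col]
            total += weights[k] * -math.log(max(probs[k, r, col], 1e-12))
    return total / (h * w)


def oracle_boundary_bce(p, g, pos_weight):
    total = 0.0
    h, w = p.shape
    for r in range(h):
        for col in range(w):
            total += -(pos_weight * g[r, col] * math.log(max(p[r, col], 1e-12))
                       + (1 - g[r, col]) * math.log(max(1 - p[r, col], 1e-12)))
    return total / (h * w)


def oracle_bas(probs, gt, b, t):
    total = 0.0
    c, h, w = probs.shape
    for r in range(h):
        for col in range(w):
            if b[r, col] > t:
                total += -math.log(max(probs[gt[r, col], r, col], 1e-12))
    return total


def oracle_unimatch(pw, pfp, ps1, ps2, lam, mu, tau):
    c, h, w = pw.shape
    total = 0.0
    for r in range(h):
        for col in range(w):
            if pw[:, r, col].max() >= tau:
                k = int(pw[:, r, col].argmax())
                total += (lam * -math.log(max(pfp[k, r, col], 1e-12))
                          + mu / 2 * (-math.log(max(ps1[k, r, col], 1e-12))
                                      - math.log(max(ps2[k, r, col], 1e-12))))
    return total / (h * w)


# ------------------------------------------------------------ weighted CE
class TestWeightedCE:
    def test_perfect_prediction_is_zero(self):
        probs = np.zeros((2, 2, 2))
        gt = np.array([[0, 1], [1, 0]])
        for r in range(2):
            for c in range(2):
                probs[gt[r, c], r, c] = 1.0
        assert weighted_ce(probs, gt).item() < 1e-9

    def test_uniform_two_class_single_pixel(self):
        val = weighted_ce(np.full((2, 1, 1), 0.5), np.array([[0]])).item()
        assert abs(val - math.log(2)) < 1e-9

    def test_hand_summed_2x2_with_weights(self):
        # probabilities on the true class: .7 .9 / .6 .8, weights (1,2,1)
        gt = np.array([[0, 1], [2, 1]])
        probs = np.zeros((3, 2, 2))
        trues = {(0, 0): 0.7, (0, 1): 0.9, (1, 0): 0.6, (1, 1): 0.8}
        for (r, c), p in trues.items():
            probs[gt[r, c], r, c] = p
            for k in range(3):
                if k != gt[r, c]:
                    probs[k, r, c] = (1 - p) / 2
        weights = (1.0, 2.0, 1.0)
        expected = oracle_weighted_ce(probs, gt, weights)
        assert abs(weighted_ce(probs, gt, weights).item() - expected) < 1e-9

    def test_rejects_out_of_range_class(self):
        with pytest.raises(ValueError):
            weighted_ce(np.full((2, 1, 1), 0.5), np.array([[3]]))

    def test_random_maps_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            c, h, w = 3, int(rng.integers(1, 5)), int(rng.integers(1, 5))
            probs = random_probs(rng, c, h, w)
            gt = rng.integers(0, c, (h, w))
            weights = tuple(rng.random(c) + 0.1)
            got = weighted_ce(probs, gt, weights).item()
            assert abs(got - oracle_weighted_ce(probs, gt, weights)) < 1e-6


# ------------------------------------------------------------ boundary BCE
class TestBoundaryBCE:
    def test_exact_match_is_zero(self):
        g = np.array([[1.0, 0.0]])
        assert boundary_bce(g[None], g).item() < 1e-9

    def test_single_pixel_half(self):
        val = boundary_bce(np.array([[[0.5]]]), np.array([[1.0]])).item()
        assert abs(val - math.log(2)) < 1e-9

    def test_four_pixel_pos_weight_10(self):
        p = np.array([[0.9, 0.2], [0.6, 0.4]])
        g = np.array([[1.0, 0.0], [1.0, 0.0]])
        got = boundary_bce(p[None], g, pos_weight=10.0).item()
        assert abs(got - oracle_boundary_bce(p, g, 10.0)) < 1e-9

    def test_random_match_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            h, w = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            p = rng.uniform(0.01, 0.99, (h, w))
            g = rng.integers(0, 2, (h, w)).astype(float)
            pw = float(rng.uniform(0.5, 20))
            got = boundary_bce(p[None], g, pw).item()
            assert abs(got - oracle_boundary_bce(p, g, pw)) < 1e-6


# ----------------------------------------------------------------- BAS loss
class TestBASLoss:
    def test_zero_when_boundary_quiet(self):
        rng = np.random.default_rng(2)
        probs = random_probs(rng, 3, 3, 3)
        gt = rng.integers(0, 3, (3, 3))
        b = np.full((1, 3, 3), 0.5)
        assert bas_loss(probs, gt, b, t=0.8).item() == 0.0

    def test_zero_when_perfect_and_fired(self):
        probs = np.zeros((2, 2, 2))
        gt = np.array([[0, 1], [1, 0]])
        for r in range(2):
            for c in range(2):
                probs[gt[r, c], r, c] = 1.0
        b = np.ones((1, 2, 2))
        assert bas_loss(probs, gt, b, t=0.8).item() < 1e-9

    def test_single_pixel_worked_example(self):
        # b=0.9 > t=0.8, true-class probability 0.25 -> -ln 0.25
        probs = np.array([[[0.25]], [[0.75]]])
        got = bas_loss(probs, np.array([[0]]), np.array([[[0.9]]]), 0.8).item()
        assert abs(got - 1.386294) < 1e-6

    def test_random_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            c, h, w = 3, int(rng.integers(1, 5)), int(rng.integers(1, 5))
            probs = random_probs(rng, c, h, w)
            gt = rng.integers(0, c, (h, w))
            b = rng.random((1, h, w))
            t = float(rng.uniform(0.2, 0.9))
            got = bas_loss(probs, gt, b, t).item()
            assert abs(got - oracle_bas(probs, gt, b[0], t)) < 1e-6

    def test_monotone_nonincreasing_in_t(self):
        rng = np.random.default_rng(4)
        probs = random_probs(rng, 3, 4, 4)
        gt = rng.integers(0, 3, (4, 4))
        b = rng.random((1, 4, 4))
        values = [bas_loss(probs, gt, b, t).item()
                  for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a >= b_ - 1e-12 for a, b_ in zip(values, values[1:]))


# ------------------------------------------------------------ combined loss
class TestSupervisedLoss:
    def _outputs(self, h=16, w=16, seed=0):
        rng = np.random.default_rng(seed)
        return NetworkOutputs(pls=Tensor(rng.normal(size=(1, 3, h, w))),
                              pl=Tensor(rng.normal(size=(1, 3, h, w))),
                              plb=Tensor(rng.normal(size=(1, 1, h, w))))

    def test_linear_combination(self):
        out = self._outputs()
        gs = np.zeros((1, 16, 16), dtype=int)
        gb = np.zeros((1, 16, 16))
        w1 = LossWeights(lambda0=1, lambda1=1, lambda2=1, lambda3=1)
        total, comps = supervised_loss(out, gs, gb, w1)
        expected = comps["l0"] + comps["l1"] + comps["l2"] + comps["l3"]
        assert abs(total.item() - expected) < 1e-6

    def test_doubling_weights_doubles_total(self):
        out = self._outputs(seed=1)
        gs = np.zeros((1, 16, 16), dtype=int)
        gb = np.ones((1, 16, 16))
        t1, _ = supervised_loss(out, gs, gb,
                                LossWeights(lambda0=1, lambda1=1, lambda2=1,
                                            lambda3=1))
        t2, _ = supervised_loss(out, gs, gb,
                                LossWeights(lambda0=2, lambda1=2, lambda2=2,
                                            lambda3=2))
        assert abs(t2.item() - 2 * t1.item()) < 1e-5

    def test_requires_full_resolution(self):
        out = self._outputs()
        with pytest.raises(ValueError):
            supervised_loss(out, np.zeros((1, 64, 64), dtype=int),
                            np.zeros((1, 64, 64)), LossWeights())


# ------------------------------------------------------------ unimatch loss
class TestUnimatchLoss:
    def test_all_below_tau_is_exact_zero(self):
        rng = np.random.default_rng(5)
        pw = random_probs(rng, 3, 3, 3) * 0.5  # max < 0.95 guaranteed
        pw = pw / pw.sum(axis=0, keepdims=True) * 0  # uniform-ish
        pw = np.full((3, 3, 3), 1 / 3)
        others = [random_probs(rng, 3, 3, 3) for _ in range(3)]
        assert unimatch_loss(pw, *others, LossWeights(tau=0.95)).item() == 0.0

    def test_self_consistent_onehot_is_zero(self):
        pw = np.zeros((2, 2, 2))
        pw[0] = 1.0
        assert unimatch_loss(pw, pw, pw, pw, LossWeights()).item() < 1e-9

    def test_single_pixel_worked_example(self):
        pw = np.array([[[0.97]], [[0.03]]])
        pfp = np.array([[[0.8]], [[0.2]]])
        ps1 = np.array([[[0.6]], [[0.4]]])
        ps2 = np.array([[[0.97]], [[0.03]]])
        w = LossWeights(tau=0.95, lambda_fp=0.5, mu=0.5)
        got = unimatch_loss(pw, pfp, ps1, ps2, w).item()
        expected = 0.5 * -math.log(0.8) + 0.25 * (-math.log(0.6) - math.log(0.97))
        assert abs(expected - 0.246893) < 1e-6  # worked value
        assert abs(got - expected) < 1e-6

    def test_random_match_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            c, h, w = 3, int(rng.integers(1, 5)), int(rng.integers(1, 5))
            maps = [random_probs(rng, c, h, w) for _ in range(4)]
            lw = LossWeights(tau=float(rng.uniform(0.3, 0.9)),
                             lambda_fp=float(rng.uniform(0.1, 1)),
                             mu=float(rng.uniform(0.1, 1)))
            got = unimatch_loss(*maps, lw).item()
            exp = oracle_unimatch(maps[0], maps[1], maps[2], maps[3],
                                  lw.lambda_fp, lw.mu, lw.tau)
            assert abs(got - exp) < 1e-6

    def test_tau_zero_equals_plain_consistency(self):
        rng = np.random.default_rng(7)
        maps = [random_probs(rng, 3, 4, 4) for _ in range(4)]
        # tau at the smallest representable positive -> gate always open
        lw_all = LossWeights(tau=1e-9)
        got = unimatch_loss(*maps, lw_all).item()
        exp = oracle_unimatch(maps[0], maps[1], maps[2], maps[3],
                              lw_all.lambda_fp, lw_all.mu, 0.0)
        assert abs(got - exp) < 1e-6

    def test_all_losses_nonnegative(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            maps = [random_probs(rng, 2, 3, 3) for _ in range(4)]
            assert unimatch_loss(*maps, LossWeights()).item() >= 0
            gt = rng.integers(0, 2, (3, 3))
            assert weighted_ce(maps[0], gt).item() >= 0
            assert bas_loss(maps[0], gt, rng.random((1, 3, 3)), 0.5).item() >= 0


def test_loss_weights_validation():
    with pytest.raises(ValueError):
        LossWeights(lambda1=-1)
    with pytest.raises(ValueError):
        LossWeights(t=1.5)
    with pytest.raises(ValueError):
        LossWeights(tau=0.0)
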