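"""Loss components against naive loop-based transcriptions of their formulas."""

import math

import numpy as np
import pytest

from desire.autodiff import Tensor
from desire.losses import (DropoutEnsemble, LossWeights, aux_segmentation_loss,
                           difficult_region_loss, final_loss, high_dose_masks,
                           weight_map_f1, weight_map_f2)

LEVELS = [1.0, 60.0 / 70.0, 55.0 / 70.0]


# ---------------------------------------------------------------------------
# independent loop oracle (scalar python arithmetic, no numpy vectorization)
# ---------------------------------------------------------------------------

def loop_oracle(pred, d, gt, levels, w: LossWeights):
    """Naive per-voxel transcription of the weighted-regression and
    segmentation objectives; returns dict of loss components."""
    pred, gt = np.asarray(pred), np.asarray(gt)
    flat_p, flat_g = pred.ravel(), gt.ravel()
    flat_d = [x.ravel() for x in d]
    m = flat_p.size

    l_mae = sum(abs(g - p) for p, g in zip(flat_p, flat_g)) / m
    l_mse = sum((g - p) ** 2 for p, g in zip(flat_p, flat_g)) / m

    l_dr = 0.0
    for i in range(m):
        vals = [x[i] for x in flat_d]
        mean = sum(vals) / 4.0
        var = sum((v - mean) ** 2 for v in vals) / 4.0
        f1 = var / (w.alpha + var)
        err = abs(mean - flat_g[i])
        f2 = err / (w.beta + err)
        l_dr += (f1 + f2) * (flat_g[i] - flat_p[i]) ** 2
    l_dr /= m

    tau = w.seg_temperature_gy / 70.0
    terms = []
    for level in levels:
        mask = [1.0 if g >= level else 0.0 for g in flat_g]
        if sum(mask) == 0:
            continue
        bce = dice_num = p_sum = 0.0
        for p, t in zip(flat_p, mask):
            prob = 1.0 / (1.0 + math.exp(-(p - level) / tau))
            prob = min(max(prob, 1e-7), 1.0 - 1e-7)
            bce += -(t * math.log(prob) + (1 - t) * math.log(1 - prob))
            dice_num += prob * t
            p_sum += prob
        bce /= m
        dice = 1.0 - (2 * dice_num + 1e-5) / (p_sum + sum(mask) + 1e-5)
        terms.append(0.5 * bce + 0.5 * dice)
    l_seg = sum(terms) / len(terms) if terms else 0.0
    return {"l_mae": l_mae, "l_mse": l_mse, "l_dr": l_dr, "l_seg": l_seg,
            "l_final": l_mae + l_dr + w.gamma * l_seg, "k": len(terms)}


def random_inputs(rng, shape):
    gt = rng.uniform(0, 1.1, shape)
    pred = gt + rng.normal(0, 0.1, shape)
    d = [pred + rng.normal(0, 0.05, shape) for _ in range(4)]
    return pred, d, gt


# ---------------------------------------------------------------------------
# weight maps
# ---------------------------------------------------------------------------

def test_f1_zero_when_ensemble_agrees(rng):
    x = rng.random((3, 3, 3))
    ens = DropoutEnsemble(x, x, x, x)
    np.testing.assert_allclose(weight_map_f1(ens, 0.5), 0.0)


def test_f1_half_at_alpha():
    # variance of {0, 1, 0, 1} is 0.25; with alpha = 0.25, f1 = 1/2
    z, o = np.zeros((2, 2, 2)), np.ones((2, 2, 2))
    ens = DropoutEnsemble(z, o, z, o)
    np.testing.assert_allclose(ens.var_d, 0.25)
    np.testing.assert_allclose(weight_map_f1(ens, alpha=0.25), 0.5)


def test_f2_limits(rng):
    gt = rng.random((3, 3, 3))
    ens = DropoutEnsemble(gt, gt, gt, gt)
    np.testing.assert_allclose(weight_map_f2(ens, gt, 0.05), 0.0)
    shifted = DropoutEnsemble(gt + 0.05, gt + 0.05, gt + 0.05, gt + 0.05)
    np.testing.assert_allclose(weight_map_f2(shifted, gt, beta=0.05), 0.5)
    far = DropoutEnsemble(gt + 1e6, gt + 1e6, gt + 1e6, gt + 1e6)
    assert np.all(weight_map_f2(far, gt, 0.05) > 1 - 1e-4)


def test_weight_maps_strictly_below_one(rng):
    pred, d, gt = random_inputs(rng, (4, 4, 4))
    ens = DropoutEnsemble(*d)
    assert np.all(weight_map_f1(ens, 0.5) < 1)
    assert np.all(weight_map_f2(ens, gt, 0.05) < 1)


def test_f1_monotone_in_variance(rng):
    variances = np.sort(rng.random(20))
    f1 = variances / (0.5 + variances)
    assert np.all(np.diff(f1) >= 0)
    # same law via the ensemble: scale one member pair to set the variance
    base = np.zeros((1, 1, 1))
    vals = []
    for s in (0.1, 0.2, 0.4):
        ens = DropoutEnsemble(base + s, base - s, base + s, base - s)
        vals.append(weight_map_f1(ens, 0.5)[0, 0, 0])
    assert vals[0] < vals[1] < vals[2]


# ---------------------------------------------------------------------------
# loss components
# ---------------------------------------------------------------------------

def test_difficult_region_loss_zero_cases(rng):
    gt = rng.random((3, 3, 3))
    ens = DropoutEnsemble(*[gt + rng.normal(0, 0.1, gt.shape) for _ in range(4)])
    assert difficult_region_loss(gt, ens, gt) == 0.0        # pred = gt
    perfect = DropoutEnsemble(gt, gt, gt, gt)               # f1 = f2 = 0
    pred = gt + rng.normal(0, 0.2, gt.shape)
    assert difficult_region_loss(pred, perfect, gt) == 0.0


def test_difficult_region_loss_matches_loop_oracle(rng):
    w = LossWeights()
    pred, d, gt = random_inputs(rng, (2, 2, 2))
    expected = loop_oracle(pred, d, gt, LEVELS, w)["l_dr"]
    got = difficult_region_loss(pred, DropoutEnsemble(*d), gt, w)
    assert got == pytest.approx(expected, rel=1e-6)


def test_ldr_bounded_by_twice_mse(rng):
    w = LossWeights()
    for _ in range(10):
        pred, d, gt = random_inputs(rng, (4, 4, 4))
        ldr = difficult_region_loss(pred, DropoutEnsemble(*d), gt, w)
        assert ldr <= 2.0 * np.mean((gt - pred) ** 2) + 1e-12


def test_high_dose_masks():
    uniform = np.full((3, 3, 3), 1.0)
    regions = high_dose_masks(uniform, [1.0])
    assert len(regions) == 1 and regions[0].mask.all()      # >= includes equality
    assert high_dose_masks(np.full((3, 3, 3), 0.5), [1.0]) == []
    with pytest.raises(ValueError):
        high_dose_masks(uniform, [0.8, 0.9])                # not descending


def test_high_dose_masks_nested_on_phantom(small_case):
    from desire.preprocess import normalize_dose
    gt = normalize_dose(small_case.dose).values
    regions = high_dose_masks(gt, LEVELS)
    assert len(regions) == 3
    counts = [int(r.mask.sum()) for r in regions]
    assert counts == sorted(counts)                          # nested by threshold
    for tight, loose in zip(regions, regions[1:]):
        assert not (tight.mask & ~loose.mask).any()


def test_aux_segmentation_loss_limits(rng):
    gt = np.full((3, 3, 3), 1.05)
    pred_far = np.full((3, 3, 3), 5.0)                       # prob -> 1 everywhere
    assert aux_segmentation_loss(pred_far, gt, [1.0]) == pytest.approx(0.0, abs=1e-4)
    cold = np.full((3, 3, 3), 0.5)
    assert aux_segmentation_loss(rng.random((3, 3, 3)), cold, [1.0]) == 0.0  # k = 0


def test_aux_segmentation_loss_matches_loop_oracle(rng):
    w = LossWeights()
    pred, _, gt = random_inputs(rng, (3, 3, 3))
    expected = loop_oracle(pred, [pred] * 4, gt, [0.9], w)["l_seg"]
    got = aux_segmentation_loss(pred, gt, [0.9], w)
    assert got == pytest.approx(expected, rel=1e-6)


def test_final_loss_composition(rng):
    w = LossWeights()
    pred, d, gt = random_inputs(rng, (4, 4, 4))
    bd = final_loss(pred, DropoutEnsemble(*d), gt, LEVELS, w)
    assert bd.l_final == pytest.approx(bd.l_mae + bd.l_dr + w.gamma * bd.l_seg,
                                       rel=1e-9)
    ref = loop_oracle(pred, d, gt, LEVELS, w)
    for key in ("l_mae", "l_mse", "l_dr", "l_seg", "l_final"):
        assert float(getattr(bd, key)) == pytest.approx(ref[key], rel=1e-6), key
    assert bd.m == 64 and bd.k == ref["k"]

    w0 = LossWeights(gamma=0.0)
    bd0 = final_loss(pred, DropoutEnsemble(*d), gt, LEVELS, w0)
    assert bd0.l_final == pytest.approx(bd0.l_mae + bd0.l_dr, rel=1e-12)


def test_final_loss_perfect_prediction(rng):
    gt = rng.uniform(0, 0.7, (3, 3, 3))    # strictly below every level: k = 0
    bd = final_loss(gt, DropoutEnsemble(gt, gt, gt, gt), gt, LEVELS)
    assert float(bd.l_final) == pytest.approx(0.0, abs=1e-12)
    assert bd.k == 0


def test_permutation_invariance(rng):
    w = LossWeights()
    pred, d, gt = random_inputs(rng, (4, 4, 4))
    perm = rng.permutation(64)

    def shuffle(x):
        return x.ravel()[perm].reshape(4, 4, 4)

    a = final_loss(pred, DropoutEnsemble(*d), gt, LEVELS, w)
    b = final_loss(shuffle(pred), DropoutEnsemble(*[shuffle(x) for x in d]),
                   shuffle(gt), LEVELS, w)
    for key in ("l_mae", "l_dr", "l_seg", "l_final"):
        assert float(getattr(a, key)) == pytest.approx(float(getattr(b, key)),
                                                       rel=1e-9)


def test_empty_grid_rejected():
    empty = np.zeros((0,))
    with pytest.raises(ValueError):
        final_loss(empty, DropoutEnsemble(empty, empty, empty, empty), empty, LEVELS)


def test_final_loss_gradient_matches_finite_differences(rng):
    """d(L_final)/d(pred) on a 2^3 grid against central differences."""
    w = LossWeights()
    pred0, d, gt = random_inputs(rng, (2, 2, 2))
    ens = DropoutEnsemble(*d)

    t = Tensor(pred0.copy(), requires_grad=True)
    final_loss(t, ens, gt, LEVELS, w).l_final.backward()

    eps = 1e-6
    num = np.zeros_like(pred0)
    for i in range(pred0.size):
        for sign in (+1, -1):
            p = pred0.copy()
            p.flat[i] += sign * eps
            val = float(final_loss(p, ens, gt, LEVELS, w).l_final)
            num.flat[i] += sign * val / (2 * eps)
    np.testing.assert_allclose(t.grad, num, rtol=1e-3, atol=1e-9)
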