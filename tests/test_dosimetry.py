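"""DVH metrics, CI/HI, gamma analysis and the rank-sum test against oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from desire.dosimetry import (GammaParams, compute_dvh, conformity_index,
                              dose_at_volume, dvh_metrics, evaluate_case,
                              gamma_pass_rate, homogeneity_index,
                              mann_whitney_u, search_offsets_mm, structure_mae,
                              volume_at_dose)
from desire.grids import VolumeGrid


def vol(values, spacing=(2.5, 2.5, 2.5)):
    return VolumeGrid(np.asarray(values, dtype=np.float64), spacing, "DOSE_GY")


# ---------------------------------------------------------------------------
# DVH / Dx
# ---------------------------------------------------------------------------

def test_dvh_step_function():
    dose = np.full((4, 4, 4), 60.0)
    mask = np.ones((4, 4, 4), bool)
    curve = compute_dvh(dose, mask)
    assert curve.at(0.0) == 1.0
    assert curve.at(59.9) == 1.0
    assert curve.at(60.05) == 0.0


def test_dvh_two_level():
    dose = np.concatenate([np.full(32, 40.0), np.full(32, 80.0)]).reshape(4, 4, 4)
    curve = compute_dvh(dose, np.ones((4, 4, 4), bool))
    assert curve.at(60.0) == pytest.approx(0.5)


def test_dvh_counting_oracle(rng):
    dose = rng.uniform(0, 80, (5, 5, 5))
    mask = rng.random((5, 5, 5)) > 0.4
    curve = compute_dvh(dose, mask, bin_width_gy=0.05)
    vals = dose[mask]
    for d in vals[:20]:
        idx = np.searchsorted(curve.dose_edges_gy, d, side="right") - 1
        edge = curve.dose_edges_gy[idx]
        assert curve.cum_volume_fraction[idx] == pytest.approx(
            np.mean(vals >= edge))


def test_dx_uniform_field():
    dose = np.full((3, 3, 3), 70.0)
    mask = np.ones((3, 3, 3), bool)
    assert dose_at_volume(dose, mask, 95) == 70.0
    assert dose_at_volume(dose, mask, 2) == 70.0


def test_d50_interpolated():
    # voxel doses 10..100: D50 = 55 Gy by sort-and-interpolate
    dose = np.arange(10.0, 101.0, 10.0).reshape(1, 2, 5)[..., :]
    dose = np.arange(10.0, 101.0, 10.0).reshape(2, 5, 1)
    mask = np.ones_like(dose, bool)
    assert dose_at_volume(dose, mask, 50) == pytest.approx(55.0)


@pytest.mark.parametrize("x", [1, 2, 50, 95, 98])
def test_dx_sort_interpolate_oracle(x, rng):
    dose = rng.uniform(0, 80, (6, 6, 6))
    mask = rng.random((6, 6, 6)) > 0.3
    vals = np.sort(dose[mask])
    # (100-x)th percentile, linear interpolation between order statistics
    q = (100.0 - x) / 100.0 * (vals.size - 1)
    lo = int(np.floor(q))
    frac = q - lo
    expected = vals[lo] * (1 - frac) + vals[min(lo + 1, vals.size - 1)] * frac
    assert dose_at_volume(dose, mask, x) == pytest.approx(expected, abs=1e-9)


def test_dx_ordering(rng):
    for _ in range(10):
        dose = rng.uniform(0, 80, (5, 5, 5))
        mask = rng.random((5, 5, 5)) > 0.5
        m = dvh_metrics(dose, mask)
        assert m.d98 <= m.d95 <= m.d50 <= m.d2 <= m.dmax
        assert dose[mask].min() <= m.dmean <= m.dmax


def test_volume_at_dose():
    mask = np.ones((2, 2, 2), bool)
    assert volume_at_dose(np.full((2, 2, 2), 60.0), mask, 30) == 100.0
    assert volume_at_dose(np.full((2, 2, 2), 10.0), mask, 30) == 0.0
    half = np.concatenate([np.full(4, 40.0), np.full(4, 20.0)]).reshape(2, 2, 2)
    assert volume_at_dose(half, mask, 30) == 50.0


def test_structure_mae(rng):
    gt = rng.uniform(0, 70, (4, 4, 4))
    mask = rng.random((4, 4, 4)) > 0.5
    assert structure_mae(gt, gt, mask) == 0.0
    assert structure_mae(gt + 2.0, gt, mask) == pytest.approx(2.0)
    pred = gt + rng.normal(0, 1, gt.shape)
    expected = sum(abs(p - g) for p, g in zip(pred[mask], gt[mask])) / mask.sum()
    assert structure_mae(pred, gt, mask) == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# CI / HI
# ---------------------------------------------------------------------------

def test_ci_closed_forms():
    shape = (8, 8, 8)
    ptv = np.zeros(shape, bool)
    ptv[2:5, 2:5, 2:5] = True
    body = np.ones(shape, bool)
    dose = np.where(ptv, 70.0, 0.0)
    assert conformity_index(dose, ptv, body, 70.0) == pytest.approx(1.0)
    assert conformity_index(np.zeros(shape), ptv, body, 70.0) == 0.0
    # prescription region twice the PTV, fully covering it -> CI = 0.5
    region = np.zeros(shape, bool)
    region[2:5, 2:5, 2:8] = True
    assert region.sum() == 2 * ptv.sum()
    dose2 = np.where(region, 70.0, 0.0)
    assert conformity_index(dose2, ptv, body, 70.0) == pytest.approx(0.5)


def test_ci_one_iff_exact_match(rng):
    shape = (6, 6, 6)
    ptv = np.zeros(shape, bool)
    ptv[1:4, 1:4, 1:4] = True
    body = np.ones(shape, bool)
    exact = np.where(ptv, 70.0, 10.0)
    assert conformity_index(exact, ptv, body, 70.0) == 1.0
    smaller = np.where(ptv, 70.0, 10.0)
    smaller[1, 1, 1] = 10.0                      # one cold voxel inside the PTV
    assert conformity_index(smaller, ptv, body, 70.0) < 1.0


def test_hi_uniform_and_scaling(rng):
    mask = np.ones((4, 4, 4), bool)
    assert homogeneity_index(np.full((4, 4, 4), 70.0), mask) == 0.0
    dose = rng.uniform(66.5, 73.5, (4, 4, 4))
    hi = homogeneity_index(dose, mask)
    d = np.sort(dose.ravel())
    oracle = (np.percentile(d, 98) - np.percentile(d, 2)) / np.percentile(d, 50)
    assert hi == pytest.approx(oracle, abs=1e-12)
    assert homogeneity_index(3.0 * dose, mask) == pytest.approx(hi, rel=1e-12)


# ---------------------------------------------------------------------------
# gamma analysis
# ---------------------------------------------------------------------------

def oracle_trilerp(vol, pts_mm, spacing):
    """Own trilinear interpolation at physical points (corner gather)."""
    shape = np.array(vol.shape)
    f = pts_mm / spacing
    lo = np.clip(np.floor(f).astype(int), 0, shape - 1)
    hi = np.minimum(lo + 1, shape - 1)
    w = f - lo
    out = np.zeros(len(f))
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                iz = hi[:, 0] if dz else lo[:, 0]
                iy = hi[:, 1] if dy else lo[:, 1]
                ix = hi[:, 2] if dx else lo[:, 2]
                wt = ((w[:, 0] if dz else 1 - w[:, 0])
                      * (w[:, 1] if dy else 1 - w[:, 1])
                      * (w[:, 2] if dx else 1 - w[:, 2]))
                out += wt * vol[iz, iy, ix]
    return out


def brute_force_gamma(gt, pred, params, spacing):
    """Exhaustive oracle: every lattice offset for every voxel — no pruning,
    no early exit, own interpolation."""
    spacing = np.asarray(spacing, float)
    offsets = search_offsets_mm(params)
    crit = params.dose_criterion_pct / 100 * params.reference_dose_gy
    thr = params.threshold_pct / 100 * params.reference_dose_gy
    upper = (np.array(gt.shape) - 1) * spacing

    voxels = np.argwhere(gt >= thr)
    coords_mm = voxels * spacing
    gt_vals = gt[gt >= thr]
    best = np.full(len(voxels), np.inf)
    for off in offsets:
        pts = coords_mm + off
        inside = np.all((pts >= -1e-9) & (pts <= upper + 1e-9), axis=1)
        if not inside.any():
            continue
        interp = oracle_trilerp(pred, pts[inside], spacing)
        g2 = (np.linalg.norm(off) / params.dta_mm) ** 2 \
            + ((interp - gt_vals[inside]) / crit) ** 2
        best[inside] = np.minimum(best[inside], g2)
    return {tuple(v): g for v, g in zip(voxels, np.sqrt(best))}


def test_gamma_identity():
    gt = vol(np.random.default_rng(0).uniform(0, 70, (6, 6, 6)))
    res = gamma_pass_rate(gt, gt)
    assert res.pass_rate == 1.0
    assert np.all(res.gamma_map[res.eval_mask] == 0.0)


def test_gamma_absorbs_one_voxel_shift(rng):
    vals = rng.uniform(20, 70, (8, 8, 8))
    vals = __import__("scipy.ndimage", fromlist=["gaussian_filter"]).gaussian_filter(vals, 1.5)
    shifted = np.roll(vals, 1, axis=2)
    # interior region only, so the rolled wrap-around column is not evaluated
    region = np.zeros_like(vals, bool)
    region[:, :, 2:-2] = True
    res = gamma_pass_rate(vol(vals), vol(shifted), region_mask=region)
    assert res.pass_rate == 1.0  # 2.5-mm shift absorbed by the 3-mm DTA


def test_gamma_matches_brute_force_oracle(rng):
    params = GammaParams()
    for trial in range(3):
        shape = tuple(rng.integers(5, 9, 3))
        gt = rng.uniform(0, 75, shape)
        pred = gt + rng.normal(0, 2.0, shape)
        res = gamma_pass_rate(vol(gt), vol(pred), params)
        oracle = brute_force_gamma(gt, pred, params, (2.5, 2.5, 2.5))
        got = {tuple(v): res.gamma_map[tuple(v)] for v in np.argwhere(res.eval_mask)}
        assert set(got) == set(oracle)
        for vox, g in oracle.items():
            assert got[vox] == pytest.approx(g, abs=1e-9)
        # identical pass sets, not just rates
        assert {v for v, g in got.items() if g <= 1.0} \
            == {v for v, g in oracle.items() if g <= 1.0}


def test_gamma_monotone_in_criteria(rng):
    gt = rng.uniform(0, 75, (7, 7, 7))
    pred = gt + rng.normal(0, 2.5, (7, 7, 7))
    tight = gamma_pass_rate(vol(gt), vol(pred), GammaParams())
    loose = gamma_pass_rate(vol(gt), vol(pred),
                            GammaParams(dose_criterion_pct=4.0, dta_mm=4.0))
    assert loose.pass_rate >= tight.pass_rate


def test_gamma_threshold_excludes_low_dose(rng):
    gt = np.full((6, 6, 6), 3.0)      # below 7 Gy = 10% of 70 Gy
    gt[2:4, 2:4, 2:4] = 50.0
    res = gamma_pass_rate(vol(gt), vol(gt))
    assert res.n_evaluated == 8
    with pytest.raises(ValueError):
        gamma_pass_rate(vol(np.full((4, 4, 4), 3.0)), vol(np.full((4, 4, 4), 3.0)))


def test_gamma_requires_spacing():
    arr = np.full((6, 6, 6), 50.0)
    with pytest.raises(ValueError, match="spacing"):
        gamma_pass_rate(arr, arr)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def enumeration_oracle(a, b):
    """Independent brute-force two-sided p: all C(n1+n2, n1) labelings."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    mu = n1 * len(b) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    devs = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        devs.append(abs(u - mu))
    devs = np.array(devs)
    return u_obs, np.mean(devs >= abs(u_obs - mu) - 1e-12)


def test_mw_identical_samples():
    _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == pytest.approx(1.0)
    _, p2 = mann_whitney_u([5.0] * 4, [5.0] * 6)
    assert p2 == 1.0


def test_mw_complete_separation():
    u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)  # 2/C(6,3)


def test_mw_exact_matches_enumeration(rng):
    for _ in range(20):
        n1, n2 = rng.integers(2, 6, 2)
        a = np.round(rng.normal(0, 1, n1), 1)   # rounding provokes ties
        b = np.round(rng.normal(0.8, 1, n2), 1)
        u, p = mann_whitney_u(a, b, method="exact")
        u_ref, p_ref = enumeration_oracle(a, b)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref, abs=1e-12)


def test_mw_asymptotic_matches_scipy_large_n(rng):
    a = rng.normal(0, 1, 25)
    b = rng.normal(0.4, 1, 30)
    u, p = mann_whitney_u(a, b)           # auto -> asymptotic at this size
    ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    assert u == pytest.approx(float(ref.statistic))
    assert p == pytest.approx(float(ref.pvalue), abs=1e-12)


# ---------------------------------------------------------------------------
# case report
# ---------------------------------------------------------------------------

def test_evaluate_case_identity(small_case):
    rep = evaluate_case(small_case.dose, small_case.dose, small_case.structures,
                        small_case.prescription)
    mae_rows = rep[rep.metric == "MAE"]
    assert np.allclose(mae_rows["diff"], 0.0)
    gamma_rows = rep[rep.metric == "gamma_pass_rate"]
    assert np.allclose(gamma_rows["pred"], 1.0)
    diff_rows = rep[~rep.metric.isin(["MAE", "gamma_pass_rate"])]
    assert np.allclose(diff_rows["diff"], 0.0)


def test_evaluate_case_row_count(small_case):
    rep = evaluate_case(small_case.dose, small_case.dose, small_case.structures,
                        small_case.prescription)
    n_ptv, n_oar = 3, 2
    expected = n_ptv * (7 + 1) + n_oar * (3 + 1) + 5  # metrics+MAE, gamma rows
    assert len(rep) == expected


def test_evaluate_case_missing_structure(small_case):
    partial = small_case.structures.subset(["PTV70", "PTV60", "BODY"])
    rep = evaluate_case(small_case.dose, small_case.dose, partial,
                        small_case.prescription)
    assert rep.attrs["missing"] == ["PTV55"]
    assert (rep.structure == "PTV70").any()


def test_evaluate_case_noise_mae(small_case, rng):
    """MAE of GT + N(0, 1 Gy) approaches E|N(0,1)| = sqrt(2/pi) = 0.798 Gy."""
    noisy = small_case.dose.with_values(
        small_case.dose.values + rng.normal(0, 1.0, small_case.dose.shape))
    rep = evaluate_case(noisy, small_case.dose, small_case.structures,
                        small_case.prescription)
    body_mae = rep[(rep.structure == "PTV55") & (rep.metric == "MAE")]["diff"].item()
    assert body_mae == pytest.approx(np.sqrt(2 / np.pi), abs=0.05)
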