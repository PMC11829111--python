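"""Dosimetric evaluation: DVH metrics, MAE, CI, HI, 3-D gamma, Mann-Whitney U.

Conventions
-----------
* ``Dx`` is the minimum dose received by the hottest x% of a structure —
  the (100 − x)th percentile of its voxel doses with linear interpolation
  (the standard ICRU reading).
* ``Vx`` is the percentage of the structure receiving at least x Gy.
* Conformity index (ideal 1): ``CI = (Vref / Vptv) * (Vref / Vpres)`` where
  ``Vref`` is the PTV volume covered by the prescription isodose and
  ``Vpres`` the in-body prescription isodose volume.
* Homogeneity index (ideal 0): ``HI = (D2 − D98) / D50``.
* Gamma analysis is global 3-D: reference (ground truth) voxels at or above
  10% of the 70 Gy prescription are scored by the minimum over displacements
  ``Δ`` (trilinear interpolation of the evaluated dose on a sub-voxel search
  lattice) of ``sqrt((|Δ|/dta)^2 + (ΔD / (3% x 70 Gy))^2)``; a voxel passes
  when that minimum is <= 1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grids import PTV_NAMES, StructureSet, VolumeGrid

__all__ = [
    "DVHCurve", "DVHMetrics", "GammaParams", "GammaResult", "ConformityInputs",
    "conformity_inputs",
    "compute_dvh", "dose_at_volume", "volume_at_dose", "structure_mae",
    "conformity_index", "homogeneity_index", "gamma_pass_rate",
    "mann_whitney_u", "dvh_metrics", "evaluate_case",
]

Dose = Union[VolumeGrid, np.ndarray]


def _values(dose: Dose) -> np.ndarray:
    return dose.values if isinstance(dose, VolumeGrid) else np.asarray(dose, dtype=np.float64)


def _masked(dose: Dose, mask: np.ndarray, what: str = "structure") -> np.ndarray:
    vals = _values(dose)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vals.shape:
        raise ValueError(f"{what} mask shape {mask.shape} does not match dose {vals.shape}")
    if not mask.any():
        raise ValueError(f"empty mask for {what}")
    return vals[mask]


# ---------------------------------------------------------------------------
# DVH and point metrics
# ---------------------------------------------------------------------------

@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of the structure receiving >= each dose edge."""

    dose_edges_gy: np.ndarray
    cum_volume_fraction: np.ndarray

    def at(self, dose_gy: float) -> float:
        """Fraction of the structure receiving at least ``dose_gy``.

        Looks up the smallest tabulated edge at or above the query, so a
        query beyond the maximum dose reports 0 and a query at 0 reports 1.
        """
        idx = int(np.searchsorted(self.dose_edges_gy, dose_gy, side="left"))
        if idx >= self.cum_volume_fraction.size:
            return 0.0
        return float(self.cum_volume_fraction[idx])


@dataclass
class DVHMetrics:
    d98: float
    d95: float
    d50: float
    d2: float
    d1: float
    dmean: float
    dmax: float
    v30: float  # % of structure receiving >= 30 Gy


def compute_dvh(dose: Dose, mask: np.ndarray, bin_width_gy: float = 0.1,
                name: str = "structure") -> DVHCurve:
    """Cumulative DVH over the masked voxels on a regular dose grid."""
    if bin_width_gy <= 0:
        raise ValueError("bin_width_gy must be > 0")
    doses = np.sort(_masked(dose, mask, name))
    top = max(doses[-1], 0.0) + 2 * bin_width_gy
    edges = np.arange(0.0, top + bin_width_gy, bin_width_gy)
    frac = 1.0 - np.searchsorted(doses, edges, side="left") / doses.size
    return DVHCurve(edges, frac)


def dose_at_volume(dose: Dose, mask: np.ndarray, x_pct: float) -> float:
    """Dx: minimum dose to the hottest x% — the (100−x)th linear percentile."""
    if not 0 < x_pct < 100:
        raise ValueError(f"x_pct must be in (0, 100), got {x_pct}")
    return float(np.percentile(_masked(dose, mask), 100.0 - x_pct, method="linear"))


def volume_at_dose(dose: Dose, mask: np.ndarray, level_gy: float) -> float:
    """Vx: percentage of the structure receiving at least ``level_gy``."""
    vals = _masked(dose, mask)
    return float(100.0 * np.mean(vals >= level_gy))


def structure_mae(pred_dose: Dose, gt_dose: Dose, mask: np.ndarray) -> float:
    """Mean absolute voxel difference within the structure, in Gy."""
    pred = _masked(pred_dose, mask, "pred")
    gt = _masked(gt_dose, mask, "gt")
    return float(np.mean(np.abs(pred - gt)))


def dvh_metrics(dose: Dose, mask: np.ndarray) -> DVHMetrics:
    vals = _masked(dose, mask)
    return DVHMetrics(
        d98=dose_at_volume(dose, mask, 98), d95=dose_at_volume(dose, mask, 95),
        d50=dose_at_volume(dose, mask, 50), d2=dose_at_volume(dose, mask, 2),
        d1=dose_at_volume(dose, mask, 1), dmean=float(vals.mean()),
        dmax=float(vals.max()), v30=volume_at_dose(dose, mask, 30.0),
    )


@dataclass(frozen=True)
class ConformityInputs:
    """The three volumes entering CI: irradiated PTV volume at prescription,
    PTV volume, and the in-body prescription isodose volume (voxel counts)."""

    v_ref: float
    v_ptv: float
    v_pres: float

    def __post_init__(self) -> None:
        if self.v_ref > min(self.v_ptv, self.v_pres) + 1e-9:
            raise ValueError("v_ref cannot exceed v_ptv or v_pres")


def conformity_inputs(dose: Dose, ptv_mask: np.ndarray, body_mask: np.ndarray,
                      prescription_gy: float) -> ConformityInputs:
    if prescription_gy <= 0:
        raise ValueError("prescription must be > 0")
    vals = _values(dose)
    ptv = np.asarray(ptv_mask, dtype=bool)
    body = np.asarray(body_mask, dtype=bool)
    if not ptv.any():
        raise ValueError("empty PTV mask")
    iso = vals >= prescription_gy
    return ConformityInputs(v_ref=float((iso & ptv).sum()),
                            v_ptv=float(ptv.sum()),
                            v_pres=float((iso & body).sum()))


def conformity_index(dose: Dose, ptv_mask: np.ndarray, body_mask: np.ndarray,
                     prescription_gy: float) -> float:
    """``CI = (Vref/Vptv) * (Vref/Vpres)`` on voxel counts (common spacing)."""
    ci = conformity_inputs(dose, ptv_mask, body_mask, prescription_gy)
    if ci.v_pres == 0:
        warnings.warn("prescription isodose region is empty; CI defined as 0")
        return 0.0
    return (ci.v_ref / ci.v_ptv) * (ci.v_ref / ci.v_pres)


def homogeneity_index(dose: Dose, ptv_mask: np.ndarray) -> float:
    """``HI = (D2 − D98) / D50`` (0 is perfectly homogeneous)."""
    d50 = dose_at_volume(dose, ptv_mask, 50)
    if d50 <= 0:
        raise ValueError("D50 must be > 0 for the homogeneity index")
    return (dose_at_volume(dose, ptv_mask, 2) - dose_at_volume(dose, ptv_mask, 98)) / d50


# ---------------------------------------------------------------------------
# gamma analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaParams:
    dose_criterion_pct: float = 3.0
    dta_mm: float = 3.0
    threshold_pct: float = 10.0
    reference_dose_gy: float = 70.0
    mode: str = "global"
    search_radius_factor: float = 3.0   # search radius = factor * dta
    search_step_divisor: float = 3.0    # lattice step = dta / divisor

    def __post_init__(self) -> None:
        for name in ("dose_criterion_pct", "dta_mm", "threshold_pct",
                     "reference_dose_gy", "search_radius_factor", "search_step_divisor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.mode != "global":
            raise ValueError("only global gamma analysis is implemented")


@dataclass
class GammaResult:
    pass_rate: float
    gamma_map: np.ndarray     # gamma where evaluated, 0 elsewhere
    n_evaluated: int
    eval_mask: np.ndarray


def search_offsets_mm(params: GammaParams) -> np.ndarray:
    """The displacement lattice: step dta/divisor, ball radius factor*dta,
    sorted by distance (Δ = 0 first)."""
    step = params.dta_mm / params.search_step_divisor
    radius = params.search_radius_factor * params.dta_mm
    k_max = int(np.floor(radius / step))
    ks = np.arange(-k_max, k_max + 1)
    offsets = np.array(list(itertools.product(ks, ks, ks)), dtype=np.float64) * step
    dists = np.linalg.norm(offsets, axis=1)
    keep = dists <= radius + 1e-12
    offsets, dists = offsets[keep], dists[keep]
    order = np.argsort(dists, kind="stable")
    return offsets[order]


def _spacing_of(dose: Dose, spacing_mm) -> Tuple[float, float, float]:
    if spacing_mm is not None:
        return tuple(float(s) for s in spacing_mm)
    if isinstance(dose, VolumeGrid):
        return dose.spacing_mm
    raise ValueError("voxel spacing is required for gamma analysis")


def gamma_pass_rate(gt_dose: Dose, pred_dose: Dose,
                    params: GammaParams = GammaParams(),
                    region_mask: Optional[np.ndarray] = None,
                    spacing_mm: Optional[Sequence[float]] = None) -> GammaResult:
    """Global 3-D gamma of the prediction against the ground truth.

    Voxels below ``threshold_pct`` of the reference dose (on the GT) are
    excluded; ``region_mask`` restricts the evaluation further.  The minimum
    over the displacement lattice is exact — offsets are visited in order of
    increasing distance and a voxel is only skipped once its distance term
    alone exceeds the current minimum, which cannot change the minimum.
    """
    spacing = np.array(_spacing_of(gt_dose, spacing_mm))
    gt = _values(gt_dose)
    pred = _values(pred_dose)
    if gt.shape != pred.shape:
        raise ValueError(f"dose grids disagree: {gt.shape} vs {pred.shape}")

    threshold = params.threshold_pct / 100.0 * params.reference_dose_gy
    crit = params.dose_criterion_pct / 100.0 * params.reference_dose_gy
    eval_mask = gt >= threshold
    if region_mask is not None:
        region_mask = np.asarray(region_mask, dtype=bool)
        if region_mask.shape != gt.shape:
            raise ValueError("region mask shape mismatch")
        eval_mask &= region_mask
        if not eval_mask.any():
            raise ValueError("region mask is empty after dose thresholding")
    if not eval_mask.any():
        raise ValueError("no voxels above the dose threshold")

    coords_vox = np.argwhere(eval_mask).astype(np.float64)        # (N, 3)
    coords_mm = coords_vox * spacing
    gt_vals = gt[eval_mask]
    upper_mm = (np.array(gt.shape) - 1) * spacing

    offsets = search_offsets_mm(params)
    dist2 = (np.linalg.norm(offsets, axis=1) / params.dta_mm) ** 2

    best = np.full(gt_vals.shape, np.inf)
    active = np.arange(gt_vals.size)
    for off, d2 in zip(offsets, dist2):
        if active.size == 0:
            break
        # distance term alone already exceeds the running minimum: done forever
        # (offsets are sorted by distance)
        keep = best[active] > d2
        active = active[keep]
        if active.size == 0:
            break
        pts = coords_mm[active] + off
        inside = np.all((pts >= -1e-9) & (pts <= upper_mm + 1e-9), axis=1)
        sel = active[inside]
        if sel.size == 0:
            continue
        pts_vox = (coords_mm[sel] + off) / spacing
        interp = ndimage.map_coordinates(pred, pts_vox.T, order=1, mode="nearest")
        g2 = d2 + ((interp - gt_vals[sel]) / crit) ** 2
        best[sel] = np.minimum(best[sel], g2)

    gamma = np.sqrt(best)
    gamma_map = np.zeros_like(gt)
    gamma_map[eval_mask] = gamma
    n_eval = int(gt_vals.size)
    return GammaResult(pass_rate=float(np.mean(gamma <= 1.0)), gamma_map=gamma_map,
                       n_evaluated=n_eval, eval_mask=eval_mask)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([a, b]))  # midranks for ties
    return float(ranks[:a.size].sum() - a.size * (a.size + 1) / 2.0)


def mann_whitney_u(sample_a: Sequence[float], sample_b: Sequence[float],
                   method: str = "auto") -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for sample_a, p).

    ``method``: "exact" enumerates all C(n1+n2, n1) labelings (midrank ties
    supported); "asymptotic" uses the tie- and continuity-corrected normal
    approximation; "auto" picks exact when both samples have <= 8 values.
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples need at least one value")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0

    u = _u_statistic(a, b)
    if method == "auto":
        method = "exact" if max(a.size, b.size) <= 8 else "asymptotic"
    if method == "exact":
        n1, n = a.size, pooled.size
        ranks = stats.rankdata(pooled)
        mu = a.size * b.size / 2.0
        dev = abs(u - mu)
        count = total = 0
        base = n1 * (n1 + 1) / 2.0
        for combo in itertools.combinations(range(n), n1):
            u_i = ranks[list(combo)].sum() - base
            total += 1
            if abs(u_i - mu) >= dev - 1e-12:
                count += 1
        return u, count / total
    if method == "asymptotic":
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        return u, float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# case-level report
# ---------------------------------------------------------------------------

PTV_METRICS = ("D98", "D95", "D50", "D2", "Dmean", "CI", "HI")
OAR_METRICS = ("D1", "Dmean", "Dmax")


def _metric(dose: Dose, mask: np.ndarray, metric: str, body: np.ndarray,
            prescription_gy: float) -> float:
    if metric.startswith("D") and metric[1:].isdigit():
        return dose_at_volume(dose, mask, float(metric[1:]))
    if metric == "Dmean":
        return float(_masked(dose, mask).mean())
    if metric == "Dmax":
        return float(_masked(dose, mask).max())
    if metric.startswith("V") and metric[1:].isdigit():
        return volume_at_dose(dose, mask, float(metric[1:]))
    if metric == "CI":
        return conformity_index(dose, mask, body, prescription_gy)
    if metric == "HI":
        return homogeneity_index(dose, mask)
    raise ValueError(f"unknown metric {metric!r}")


def evaluate_case(pred_dose: Dose, gt_dose: Dose, structures: StructureSet,
                  prescription: Dict[str, float],
                  gamma_params: GammaParams = GammaParams(),
                  oar_metrics: Sequence[str] = OAR_METRICS,
                  l35_level_gy: float = 35.0) -> pd.DataFrame:
    """Full per-case dosimetric report as a tidy table.

    Rows: per PTV D98/D95/D50/D2/Dmean + CI + HI; per OAR D1/Dmean/Dmax (and
    any configured Vx); per-structure MAE; gamma pass rates for the body, the
    three PTVs and the GT 35-Gy isodose region (L35).  Missing structures are
    reported in ``DataFrame.attrs['missing']`` and skipped.
    """
    rows: List[Dict] = []
    missing: List[str] = []
    body = structures["BODY"] if "BODY" in structures else np.ones(_values(gt_dose).shape, bool)

    def add(structure: str, metric: str, gt_v, pred_v, diff) -> None:
        rows.append({"structure": structure, "metric": metric,
                     "gt": gt_v, "pred": pred_v, "diff": diff})

    for name in PTV_NAMES:
        if name not in structures:
            missing.append(name)
            continue
        mask = structures[name]
        for metric in PTV_METRICS:
            gv = _metric(gt_dose, mask, metric, body, prescription[name])
            pv = _metric(pred_dose, mask, metric, body, prescription[name])
            add(name, metric, gv, pv, pv - gv)
        add(name, "MAE", np.nan, np.nan, structure_mae(pred_dose, gt_dose, mask))

    oar_names = [n for n in structures.names if n not in PTV_NAMES and n != "BODY"]
    for name in oar_names:
        mask = structures[name]
        for metric in oar_metrics:
            gv = _metric(gt_dose, mask, metric, body, prescription.get(name, 70.0))
            pv = _metric(pred_dose, mask, metric, body, prescription.get(name, 70.0))
            add(name, metric, gv, pv, pv - gv)
        add(name, "MAE", np.nan, np.nan, structure_mae(pred_dose, gt_dose, mask))

    gamma_regions: List[Tuple[str, Optional[np.ndarray]]] = [("BODY", body)]
    gamma_regions += [(n, structures[n]) for n in PTV_NAMES if n in structures]
    gamma_regions.append(("L35", _values(gt_dose) >= l35_level_gy))
    for name, region in gamma_regions:
        try:
            res = gamma_pass_rate(gt_dose, pred_dose, gamma_params, region_mask=region,
                                  spacing_mm=None if isinstance(gt_dose, VolumeGrid)
                                  else structures.reference_spacing_mm)
            add(name, "gamma_pass_rate", np.nan, res.pass_rate, np.nan)
        except ValueError as exc:
            warnings.warn(f"gamma for {name} skipped: {exc}")

    report = pd.DataFrame(rows, columns=["structure", "metric", "gt", "pred", "diff"])
    report.attrs["missing"] = missing
    report.attrs["gamma_params"] = gamma_params
    return report
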