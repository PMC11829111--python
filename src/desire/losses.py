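"""Training objectives: MAE, difficult-region learning, auxiliary segmentation.

The difficult-region loss re-weights the squared error by two maps derived
from four dropout perturbations d1..d4 of the prediction:

* ``f1 = VarD / (alpha + VarD)`` — model uncertainty (variance of d1..d4),
* ``f2 = |MeanD - GT| / (beta + |MeanD - GT|)`` — ensemble error,

so voxels where the model is unsure or wrong get weight approaching 1 and
easy voxels approach 0; ``L_DR = mean((f1 + f2) * (y - yhat)^2)``.  The weight
maps are treated as constants during differentiation (gradients flow only
through the squared error), which stops the optimizer from shrinking the loss
by saturating the maps instead of fixing the prediction.

The auxiliary segmentation loss thresholds the ground-truth dose at each
prescription level (>= 70, 60, 55 Gy in normalized units) to form high-dose
region masks, converts the predicted dose to a soft occupancy via a
temperature-softened logistic at the same threshold, and scores it with
0.5 * BCE + 0.5 * Dice averaged over the non-empty regions.

``L_final = L_MAE + L_DR + gamma * L_seg`` with the defaults alpha = 0.5,
beta = 0.05, gamma = 0.1.  The plain MSE is computed alongside as a logged
diagnostic only.  All functions accept either numpy arrays or autodiff
tensors for the prediction; ground truth and the dropout ensemble are plain
arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, List, NamedTuple, Sequence, Union

import numpy as np

from .autodiff import Tensor

__all__ = [
    "LossWeights", "DropoutEnsemble", "LossBreakdown", "HighDoseRegion",
    "weight_map_f1", "weight_map_f2", "difficult_region_loss",
    "high_dose_masks", "aux_segmentation_loss", "final_loss",
]

ArrayLike = Union[np.ndarray, Tensor]

DICE_EPS = 1e-5
BCE_CLAMP = 1e-7


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 0.5
    beta: float = 0.05
    gamma: float = 0.1
    seg_temperature_gy: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.seg_temperature_gy <= 0:
            raise ValueError("seg_temperature_gy must be > 0")


@dataclass
class DropoutEnsemble:
    """The four dropout predictions with their voxelwise variance and mean."""

    d1: np.ndarray
    d2: np.ndarray
    d3: np.ndarray
    d4: np.ndarray

    def __post_init__(self) -> None:
        ds = [np.asarray(d, dtype=np.float64) for d in (self.d1, self.d2, self.d3, self.d4)]
        if len({d.shape for d in ds}) != 1:
            raise ValueError("d1..d4 must share one shape")
        self.d1, self.d2, self.d3, self.d4 = ds
        stack = np.stack(ds)
        self.mean_d: np.ndarray = stack.mean(axis=0)
        self.var_d: np.ndarray = stack.var(axis=0)  # population variance over the 4

    @classmethod
    def from_predictions(cls, preds: Sequence[ArrayLike]) -> "DropoutEnsemble":
        if len(preds) != 4:
            raise ValueError(f"expected 4 dropout predictions, got {len(preds)}")
        return cls(*[np.asarray(p) for p in preds])

    @property
    def shape(self):
        return self.d1.shape


@dataclass
class LossBreakdown:
    """Components of one training step; fields keep the autodiff graph when
    the prediction was a Tensor (use :meth:`as_floats` for logging)."""

    l_mae: Any
    l_mse: float
    l_dr: Any
    l_seg: Any
    l_final: Any
    m: int
    k: int

    def as_floats(self) -> dict:
        return {
            "l_mae": float(self.l_mae), "l_mse": float(self.l_mse),
            "l_dr": float(self.l_dr), "l_seg": float(self.l_seg),
            "l_final": float(self.l_final), "m": self.m, "k": self.k,
        }


class HighDoseRegion(NamedTuple):
    level: float           # normalized dose threshold (prescription / 70)
    mask: np.ndarray       # GT voxels at or above the level


# -- generic helpers working on both ndarray and Tensor ----------------------

def _mean(x: ArrayLike):
    return x.mean() if isinstance(x, Tensor) else float(np.mean(x))


def _sum(x: ArrayLike):
    return x.sum() if isinstance(x, Tensor) else float(np.sum(x))


def _abs(x: ArrayLike):
    return x.abs() if isinstance(x, Tensor) else np.abs(x)


def _clip(x: ArrayLike, lo: float, hi: float):
    return x.clip(lo, hi) if isinstance(x, Tensor) else np.clip(x, lo, hi)


def _log(x: ArrayLike):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def _sigmoid(x: ArrayLike):
    from scipy.special import expit
    return x.sigmoid() if isinstance(x, Tensor) else expit(x)


def _check_nonempty(x) -> None:
    if np.asarray(x).size == 0:
        raise ValueError("empty grid")


# -- weight maps --------------------------------------------------------------

def weight_map_f1(ensemble: DropoutEnsemble, alpha: float = 0.5) -> np.ndarray:
    """Uncertainty weight map ``VarD / (alpha + VarD)``, values in [0, 1)."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    var = ensemble.var_d
    if np.any(var < 0):
        raise ValueError("negative ensemble variance")
    return var / (alpha + var)


def weight_map_f2(ensemble: DropoutEnsemble, gt: np.ndarray,
                  beta: float = 0.05) -> np.ndarray:
    """Error weight map ``|MeanD - GT| / (beta + |MeanD - GT|)``, in [0, 1)."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    gt = np.asarray(gt, dtype=np.float64)
    if gt.shape != ensemble.shape:
        raise ValueError(f"GT shape {gt.shape} does not match ensemble {ensemble.shape}")
    err = np.abs(ensemble.mean_d - gt)
    return err / (beta + err)


# -- losses -------------------------------------------------------------------

def difficult_region_loss(pred: ArrayLike, ensemble: DropoutEnsemble,
                          gt: np.ndarray, weights: LossWeights = LossWeights()):
    """``mean((f1 + f2) * (gt - pred)^2)`` with f1/f2 held constant."""
    _check_nonempty(gt)
    gt = np.asarray(gt, dtype=np.float64)
    if tuple(np.shape(pred)) != gt.shape or gt.shape != ensemble.shape:
        raise ValueError("pred, GT and ensemble must share one shape")
    w = weight_map_f1(ensemble, weights.alpha) + weight_map_f2(ensemble, gt, weights.beta)
    return _mean(((gt - pred) ** 2.0) * w)


def high_dose_masks(gt_dose: np.ndarray,
                    prescription_norm: Sequence[float]) -> List[HighDoseRegion]:
    """Threshold the GT dose at each prescription level; drop empty regions."""
    gt = np.asarray(gt_dose, dtype=np.float64)
    levels = [float(v) for v in prescription_norm]
    if any(b >= a for a, b in zip(levels, levels[1:])):
        raise ValueError("prescription levels must be strictly descending")
    if any(not 0 < v <= 1.2 for v in levels):
        raise ValueError("normalized prescription levels must lie in (0, 1.2]")
    regions = []
    for level in levels:
        mask = gt >= level
        if mask.any():
            regions.append(HighDoseRegion(level, mask))
    return regions


def _bce(prob: ArrayLike, target: np.ndarray):
    p = _clip(prob, BCE_CLAMP, 1.0 - BCE_CLAMP)
    return -_mean(_log(p) * target + _log(1.0 - p) * (1.0 - target))


def _dice_loss(prob: ArrayLike, target: np.ndarray):
    inter = _sum(prob * target)
    return 1.0 - (2.0 * inter + DICE_EPS) / (_sum(prob) + float(target.sum()) + DICE_EPS)


def aux_segmentation_loss(pred_dose: ArrayLike, gt_dose: np.ndarray,
                          prescription_norm: Sequence[float],
                          weights: LossWeights = LossWeights()):
    """0.5*BCE + 0.5*Dice between the soft-thresholded prediction and each
    high-dose GT region, averaged over the non-empty regions (0 if none)."""
    regions = high_dose_masks(gt_dose, prescription_norm)
    if not regions:
        return 0.0
    tau = weights.seg_temperature_gy / 70.0
    total = None
    for level, mask in regions:
        prob = _sigmoid((pred_dose - level) * (1.0 / tau))
        target = mask.astype(np.float64)
        term = _bce(prob, target) * 0.5 + _dice_loss(prob, target) * 0.5
        total = term if total is None else total + term
    return total * (1.0 / len(regions))


def final_loss(pred: ArrayLike, ensemble: DropoutEnsemble, gt: np.ndarray,
               prescription_norm: Sequence[float],
               weights: LossWeights = LossWeights()) -> LossBreakdown:
    """``L_final = L_MAE + L_DR + gamma * L_seg`` plus the MSE diagnostic."""
    _check_nonempty(gt)
    gt = np.asarray(gt, dtype=np.float64)
    l_mae = _mean(_abs(gt - pred))
    l_mse = float(np.mean((gt - np.asarray(pred)) ** 2))  # diagnostic only
    l_dr = difficult_region_loss(pred, ensemble, gt, weights)
    l_seg = aux_segmentation_loss(pred, gt, prescription_norm, weights)
    l_final = l_mae + l_dr + l_seg * weights.gamma
    return LossBreakdown(l_mae=l_mae, l_mse=l_mse, l_dr=l_dr, l_seg=l_seg,
                         l_final=l_final, m=int(gt.size),
                         k=len(high_dose_masks(gt, prescription_norm)))
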