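"""Deterministic preprocessing: CT windowing, dose scaling, resampling, input stack.

CT values are clipped to the window (−1024, 2048) HU and mapped linearly onto
[0, 1]; doses are divided by the 70 Gy reference prescription (normalized
doses may exceed 1.0 — supra-prescription hot spots are real and the model
must represent them, so predictions are never clipped).  The model input is a
5-channel stack: normalized CT, the three PTV masks scaled by their
prescription relative to 70 Gy (1.0, 60/70, 55/70 — an ordinal dose-target
encoding), and the union of all OAR masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple
import warnings

import numpy as np

from .grids import (
    PTV_NAMES,
    StructureSet,
    VolumeGrid,
    resize_linear,
    resize_nearest,
    validate_prescription,
)

__all__ = [
    "CT_WINDOW_HU",
    "DOSE_REF_GY",
    "ModelInput",
    "PreprocessConfig",
    "normalize_ct",
    "normalize_dose",
    "denormalize_dose",
    "resample",
    "resample_mask",
    "assemble_model_input",
]

CT_WINDOW_HU = (-1024.0, 2048.0)
DOSE_REF_GY = 70.0


@dataclass(frozen=True)
class PreprocessConfig:
    ct_window: Tuple[float, float] = CT_WINDOW_HU
    dose_ref_gy: float = DOSE_REF_GY
    target_shape: Tuple[int, int, int] = (96, 128, 128)
    per_oar_channels: bool = False


@dataclass
class ModelInput:
    """Stacked network input channels (C, Z, Y, X) with their names."""

    channels: np.ndarray
    channel_names: List[str]

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 4:
            raise ValueError("ModelInput.channels must be 4-D (C, Z, Y, X)")
        if len(self.channel_names) != self.channels.shape[0]:
            raise ValueError("channel_names length must match channel count")

    @property
    def spatial_shape(self) -> Tuple[int, int, int]:
        return self.channels.shape[1:]


def normalize_ct(ct: VolumeGrid, window: Tuple[float, float] = CT_WINDOW_HU) -> VolumeGrid:
    """Clip CT to the HU window and rescale linearly onto [0, 1]."""
    if ct.kind != "CT_HU":
        raise ValueError(f"normalize_ct expects kind CT_HU, got {ct.kind}")
    lo, hi = window
    out = (np.clip(ct.values, lo, hi) - lo) / (hi - lo)
    return ct.with_values(out, "CT_NORM")


def normalize_dose(dose: VolumeGrid, ref_gy: float = DOSE_REF_GY) -> VolumeGrid:
    """Divide the dose by the reference prescription (70 Gy)."""
    if dose.kind != "DOSE_GY":
        raise ValueError(f"normalize_dose expects kind DOSE_GY, got {dose.kind}")
    if np.any(dose.values < 0):
        raise ValueError("negative dose values")
    return dose.with_values(dose.values / ref_gy, "DOSE_NORM")


def denormalize_dose(dose: VolumeGrid, ref_gy: float = DOSE_REF_GY) -> VolumeGrid:
    """Inverse of :func:`normalize_dose`: back to Gy."""
    if dose.kind != "DOSE_NORM":
        raise ValueError(f"denormalize_dose expects kind DOSE_NORM, got {dose.kind}")
    return dose.with_values(dose.values * ref_gy, "DOSE_GY")


def resample(volume: VolumeGrid, target_shape: Sequence[int],
             mode: str = "trilinear") -> VolumeGrid:
    """Resample a scalar volume to ``target_shape`` (trilinear or nearest).

    Spacing is rescaled by the shape ratio so the physical extent is preserved.
    """
    target_shape = tuple(int(n) for n in target_shape)
    if len(target_shape) != 3 or any(n < 2 for n in target_shape):
        raise ValueError(f"target_shape must be 3 ints >= 2, got {target_shape}")
    if mode not in ("trilinear", "nearest"):
        raise ValueError(f"unknown resample mode {mode!r}")
    vals = (resize_linear(volume.values, target_shape) if mode == "trilinear"
            else resize_nearest(volume.values, target_shape))
    new_spacing = tuple(s * n_in / n_out for s, n_in, n_out
                        in zip(volume.spacing_mm, volume.shape, target_shape))
    return VolumeGrid(vals, new_spacing, volume.kind)


def resample_mask(mask: np.ndarray, target_shape: Sequence[int],
                  mode: str = "nearest", force: bool = False) -> np.ndarray:
    """Resample a binary mask; trilinear is refused (downgraded) unless forced."""
    if mode == "trilinear" and not force:
        warnings.warn("trilinear resampling of a binary mask would break binarity; "
                      "using nearest (pass force=True to override)")
        mode = "nearest"
    target_shape = tuple(int(n) for n in target_shape)
    if mode == "nearest":
        return resize_nearest(mask.astype(np.uint8), target_shape).astype(bool)
    return resize_linear(mask.astype(np.float64), target_shape)


def assemble_model_input(ct_norm: VolumeGrid, structures: StructureSet,
                         prescription: Dict[str, float],
                         config: PreprocessConfig = PreprocessConfig()) -> ModelInput:
    """Stack CT + prescription-scaled PTV masks + merged (or per-) OAR channels."""
    if ct_norm.kind != "CT_NORM":
        raise ValueError("assemble_model_input expects a normalized CT (kind CT_NORM)")
    prescription = validate_prescription(prescription)
    missing = [n for n in PTV_NAMES if n not in structures]
    if missing:
        raise ValueError(f"missing PTV masks: {missing}")
    shape = ct_norm.shape
    for name, mask in structures.masks.items():
        if mask.shape != shape:
            raise ValueError(f"structure {name!r} not aligned with CT: "
                             f"{mask.shape} vs {shape}")

    channels = [ct_norm.values]
    names = ["CT"]
    for name in PTV_NAMES:
        channels.append(structures[name].astype(np.float64)
                        * (prescription[name] / config.dose_ref_gy))
        names.append(name)

    oar_names = [n for n in structures.names if n not in PTV_NAMES and n != "BODY"]
    if config.per_oar_channels:
        for name in oar_names:
            channels.append(structures[name].astype(np.float64))
            names.append(name)
    else:
        union = np.zeros(shape)
        for name in oar_names:
            union = np.maximum(union, structures[name].astype(np.float64))
        channels.append(union)
        names.append("OARS")
    return ModelInput(np.stack(channels, axis=0), names)
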