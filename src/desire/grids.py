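"""Core spatial containers: scalar volumes on a regular grid and named binary masks.

Everything downstream (preprocessing, the network, dosimetry) operates on
:class:`VolumeGrid` and :class:`StructureSet`.  A grid is a plain 3-D numpy
array (z, y, x order) plus physical voxel spacing in millimetres and a ``kind``
tag that records which physical quantity the values represent.  The kind tag
lets preprocessing refuse nonsensical operations (normalizing an
already-normalized CT, scaling a probability map by 70 Gy, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np

#: Recognised value kinds for a VolumeGrid.
KINDS = ("CT_HU", "CT_NORM", "DOSE_GY", "DOSE_NORM", "PROB")

#: Normalized doses may exceed 1.0 (supra-prescription hot spots, e.g. D2 of a
#: 70 Gy target sits near 75/70); CT_NORM and PROB may not.
DOSE_NORM_HEADROOM = 0.2


@dataclass
class VolumeGrid:
    """A 3-D scalar field with physical voxel spacing.

    Parameters
    ----------
    values
        3-D array (z, y, x).  Stored as float64.
    spacing_mm
        Voxel size per axis in millimetres, same axis order as ``values``.
    kind
        One of :data:`KINDS`.
    """

    values: np.ndarray
    spacing_mm: Tuple[float, float, float]
    kind: str = "CT_HU"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"VolumeGrid expects a 3-D array, got ndim={self.values.ndim}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown grid kind {self.kind!r}; expected one of {KINDS}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 positive reals, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("VolumeGrid values must be finite")
        # normalized kinds carry range contracts; DOSE_NORM alone gets
        # headroom above 1 (supra-prescription hot spots exist)
        if self.kind in ("CT_NORM", "PROB"):
            if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
                raise ValueError(f"{self.kind} values must lie in [0, 1]")
        elif self.kind == "DOSE_NORM":
            if self.values.min() < -1e-9 \
                    or self.values.max() > 1 + DOSE_NORM_HEADROOM:
                raise ValueError("DOSE_NORM values must lie in "
                                 f"[0, {1 + DOSE_NORM_HEADROOM}]")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.values.copy(), self.spacing_mm, self.kind)

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "VolumeGrid":
        return VolumeGrid(values, self.spacing_mm, kind or self.kind)


@dataclass
class StructureSet:
    """Named binary masks (targets, organs at risk, body) on one reference grid."""

    masks: Dict[str, np.ndarray]
    reference_spacing_mm: Tuple[float, float, float]

    def __post_init__(self) -> None:
        self.reference_spacing_mm = tuple(float(s) for s in self.reference_spacing_mm)
        shapes = set()
        clean: Dict[str, np.ndarray] = {}
        for name, mask in self.masks.items():
            arr = np.asarray(mask)
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"mask {name!r} is not binary (values {uniq[:5]}...)")
            clean[name] = arr.astype(bool)
            shapes.add(arr.shape)
        if len(shapes) > 1:
            raise ValueError(f"structure masks disagree on shape: {sorted(shapes)}")
        self.masks = clean

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(self.masks)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def subset(self, names: Iterable[str]) -> "StructureSet":
        return StructureSet({n: self.masks[n] for n in names}, self.reference_spacing_mm)


#: Prescription: mapping structure name -> prescribed dose in Gy.
Prescription = Mapping[str, float]

DEFAULT_PRESCRIPTION: Dict[str, float] = {"PTV70": 70.0, "PTV60": 60.0, "PTV55": 55.0}

PTV_NAMES = ("PTV70", "PTV60", "PTV55")


def validate_prescription(prescription: Prescription) -> Dict[str, float]:
    """Check the three nested target levels are present and strictly decreasing."""
    p = {str(k): float(v) for k, v in prescription.items()}
    missing = [n for n in PTV_NAMES if n not in p]
    if missing:
        raise ValueError(f"prescription missing target levels: {missing}")
    levels = [p[n] for n in PTV_NAMES]
    if not (levels[0] > levels[1] > levels[2] > 0):
        raise ValueError(f"prescription levels must be strictly decreasing positives, got {levels}")
    return p


# ---------------------------------------------------------------------------
# Shared linear resampling (half-voxel / align-corners-false convention)
# ---------------------------------------------------------------------------

def _axis_resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense (n_out, n_in) linear-interpolation matrix, half-pixel centres.

    Output sample i maps to source coordinate (i + 0.5) * n_in/n_out - 0.5,
    clamped to the valid range (edge replication).
    """
    if n_in < 1 or n_out < 1:
        raise ValueError("axis sizes must be >= 1")
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    w_hi = src - lo
    mat = np.zeros((n_out, n_in))
    rows = np.arange(n_out)
    np.add.at(mat, (rows, lo), 1.0 - w_hi)
    np.add.at(mat, (rows, hi), w_hi)
    return mat


def _axis_nearest_index(n_in: int, n_out: int) -> np.ndarray:
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    return np.clip(np.rint(src), 0, n_in - 1).astype(int)


def resize_linear(values: np.ndarray, target_shape: Tuple[int, int, int]) -> np.ndarray:
    """Trilinear resize of a 3-D (or leading-channel 4-D) array."""
    out = np.asarray(values, dtype=values.dtype if np.issubdtype(values.dtype, np.floating) else np.float64)
    spatial_offset = out.ndim - 3
    for ax, n_out in enumerate(target_shape):
        axis = ax + spatial_offset
        mat = _axis_resize_matrix(out.shape[axis], n_out).astype(out.dtype)
        out = np.moveaxis(np.tensordot(mat, np.moveaxis(out, axis, 0), axes=(1, 0)), 0, axis)
    return out


def resize_nearest(values: np.ndarray, target_shape: Tuple[int, int, int]) -> np.ndarray:
    """Nearest-neighbour resize; preserves the value set (binary masks stay binary)."""
    out = np.asarray(values)
    spatial_offset = out.ndim - 3
    for ax, n_out in enumerate(target_shape):
        axis = ax + spatial_offset
        idx = _axis_nearest_index(out.shape[axis], n_out)
        out = np.take(out, idx, axis=axis)
    return out
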