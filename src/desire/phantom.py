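"""Synthetic NPC-like phantom cases: CT, nested targets, OARs and a planned dose.

Real head-and-neck planning data is rarely shareable, so the package ships a
generator that emulates the geometry and plan properties the dose-prediction
task assumes:

* three nested planning target volumes (PTV70 ⊆ PTV60 ⊆ PTV55) prescribed
  70 / 60 / 55 Gy, inside a body contour, with optional organ-at-risk (OAR)
  ellipsoids placed clear of the targets;
* a ground-truth dose that covers at least 95% of every PTV at its
  prescription, keeps the PTV70 hot spot under 107% of 70 Gy, and falls off
  smoothly (logistic-of-distance) outside the targets — the standard VMAT
  optimization goals for this disease site;
* a CT whose tissue contrast makes the structures learnable from image +
  mask channels (body ≈ 40 HU, targets +30 HU, OARs −20 HU, air −1000 HU).

The dose model is ``dose(v) = max_L A_L · σ((m − d_L(v)) / w)`` where ``d_L``
is the Euclidean distance (mm) to target L, ``σ`` the logistic function,
``w`` the falloff width and ``m`` a plateau margin.  The amplitude
``A_L = 1.04 · P_L`` with ``m = 20 mm`` puts the in-target plateau at
≈ 1.02 · P_L, so D95 ≥ prescription holds with realistic (< 3%) headroom and
the 107% hot-spot bound is honoured by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import nibabel as nib
import numpy as np
from scipy import ndimage

from .grids import (
    DEFAULT_PRESCRIPTION,
    PTV_NAMES,
    StructureSet,
    VolumeGrid,
    validate_prescription,
)

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "GeometryInfeasibleError",
    "generate_phantom",
    "write_dataset",
    "read_dataset",
]


class GeometryInfeasibleError(ValueError):
    """The requested grid cannot contain the three nested targets plus margins."""


# dose-model constants (see module docstring)
DOSE_AMPLITUDE_FACTOR = 1.04
DOSE_PLATEAU_MARGIN_MM = 20.0
DOSE_FALLOFF_WIDTH_MM = 5.0
DOSE_BODY_MARGIN_MM = 15.0     # dose forced to 0 beyond this distance from body
DOSE_CAP_GY = 78.0             # physical cap, < 1.15 x 70 Gy

HU_AIR = -1000.0
HU_BODY = 40.0
HU_BODY_SD = 10.0
HU_PTV_OFFSET = 30.0
HU_OAR_OFFSET = -20.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case; equal specs generate identical cases."""

    grid_shape: Tuple[int, int, int] = (48, 64, 64)
    spacing_mm: Tuple[float, float, float] = (3.0, 2.5, 2.5)
    n_oars: int = 3
    prescription_gy: Tuple[Tuple[str, float], ...] = tuple(DEFAULT_PRESCRIPTION.items())
    noise_sd_gy: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        gs = tuple(int(g) for g in self.grid_shape)
        sp = tuple(float(s) for s in self.spacing_mm)
        object.__setattr__(self, "grid_shape", gs)
        object.__setattr__(self, "spacing_mm", sp)
        object.__setattr__(self, "prescription_gy", tuple((str(k), float(v)) for k, v in dict(self.prescription_gy).items()))
        if len(gs) != 3 or any(g < 16 for g in gs):
            raise ValueError(f"grid_shape must be 3 ints all >= 16, got {gs}")
        if len(sp) != 3 or any(not (0.5 < s < 10.0) for s in sp):
            raise ValueError(f"spacing_mm must lie in (0.5, 10) mm, got {sp}")
        if self.n_oars < 0:
            raise ValueError("n_oars must be >= 0")
        if self.noise_sd_gy < 0:
            raise ValueError("noise_sd_gy must be >= 0")
        validate_prescription(dict(self.prescription_gy))

    @property
    def prescription(self) -> Dict[str, float]:
        return dict(self.prescription_gy)

    def to_json(self) -> Dict:
        d = asdict(self)
        d["prescription_gy"] = dict(self.prescription_gy)
        return d

    @classmethod
    def from_json(cls, d: Dict) -> "PhantomSpec":
        return cls(
            grid_shape=tuple(d["grid_shape"]),
            spacing_mm=tuple(d["spacing_mm"]),
            n_oars=int(d["n_oars"]),
            prescription_gy=tuple(dict(d["prescription_gy"]).items()),
            noise_sd_gy=float(d["noise_sd_gy"]),
            seed=int(d["seed"]),
        )


@dataclass
class PhantomCase:
    """One synthetic patient: CT, structures, planned dose and its spec."""

    case_id: str
    ct: VolumeGrid
    structures: StructureSet
    dose: VolumeGrid
    spec: PhantomSpec

    @property
    def prescription(self) -> Dict[str, float]:
        return self.spec.prescription


def _ellipsoid_mask(shape: Sequence[int], spacing: Sequence[float],
                    center_mm: np.ndarray, semi_axes_mm: np.ndarray) -> np.ndarray:
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    q = ((zz - center_mm[0]) / semi_axes_mm[0]) ** 2 \
        + ((yy - center_mm[1]) / semi_axes_mm[1]) ** 2 \
        + ((xx - center_mm[2]) / semi_axes_mm[2]) ** 2
    return q <= 1.0


def generate_phantom(spec: PhantomSpec, case_id: str | None = None) -> PhantomCase:
    """Generate one phantom case deterministically from its spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    spacing = np.array(spec.spacing_mm)
    extent_mm = np.array(shape) * spacing
    prescription = spec.prescription

    # body: elliptical cylinder spanning z, cross-section 88% of the y/x extent
    body_semi = np.array([extent_mm[0], 0.44 * extent_mm[1], 0.44 * extent_mm[2]])
    body_center = extent_mm / 2.0
    body = _ellipsoid_mask(shape, spacing, body_center, body_semi)

    # concentric PTV ellipsoids: randomized shared centre and PTV70 radii,
    # 6 mm successive margins (targets expand PTV70 -> PTV60 -> PTV55)
    jitter = rng.uniform(-4.0, 4.0, size=3)
    center = body_center + jitter
    ptv70_semi = rng.uniform(10.0, 14.0, size=3)
    margins = {"PTV70": 0.0, "PTV60": 6.0, "PTV55": 12.0}
    outer_semi = ptv70_semi + margins["PTV55"]

    clearance = 2.0 * spacing  # two voxels per axis
    lo_ok = center - outer_semi - clearance
    hi_ok = center + outer_semi + clearance
    inside_body = np.all(np.abs(center - body_center) + outer_semi + clearance
                         < np.maximum(body_semi, 1e-9))
    if np.any(lo_ok < 0) or np.any(hi_ok > extent_mm) or not inside_body:
        raise GeometryInfeasibleError(
            f"geometry infeasible: nested targets (outer semi-axes {outer_semi} mm) "
            f"do not fit grid extent {extent_mm} mm with 2-voxel clearance")

    masks: Dict[str, np.ndarray] = {}
    for name in PTV_NAMES:
        masks[name] = _ellipsoid_mask(shape, spacing, center, ptv70_semi + margins[name])
    if not masks["PTV70"].any():
        raise GeometryInfeasibleError("geometry infeasible: PTV70 contains no voxels")

    # OARs: ellipsoids outside PTV55 with >= 2-voxel clearance, inside the body
    dist_ptv55 = ndimage.distance_transform_edt(~masks["PTV55"], sampling=spacing)
    dist_outside_body = ndimage.distance_transform_edt(body, sampling=spacing)
    clearance_mm = 2.0 * float(spacing.max())
    oar_names: List[str] = []
    for i in range(spec.n_oars):
        name = f"OAR{i + 1}"
        placed = False
        for _ in range(60):
            semi = rng.uniform(5.0, 9.0, size=3)
            r_max = float(semi.max())
            ok = (dist_ptv55 >= r_max + clearance_mm) & (dist_outside_body >= r_max)
            cand = np.argwhere(ok)
            if cand.size == 0:
                continue
            c_vox = cand[rng.integers(len(cand))]
            oar = _ellipsoid_mask(shape, spacing, c_vox * spacing, semi)
            if oar.any() and not (oar & masks["PTV55"]).any():
                masks[name] = oar
                oar_names.append(name)
                placed = True
                break
        if not placed:
            raise GeometryInfeasibleError(
                f"geometry infeasible: could not place {name} outside the targets")

    masks["BODY"] = body
    structures = StructureSet(masks, tuple(spec.spacing_mm))

    # dose: logistic falloff of distance to each target, max over levels
    dose = np.zeros(shape)
    for name in PTV_NAMES:
        d = ndimage.distance_transform_edt(~masks[name], sampling=spacing)
        level = DOSE_AMPLITUDE_FACTOR * prescription[name]
        dose = np.maximum(dose, level / (1.0 + np.exp(-(DOSE_PLATEAU_MARGIN_MM - d)
                                                      / DOSE_FALLOFF_WIDTH_MM)))
    if spec.noise_sd_gy > 0:
        dose = dose + rng.normal(0.0, spec.noise_sd_gy, size=shape)
    dose[ndimage.distance_transform_edt(~body, sampling=spacing) > DOSE_BODY_MARGIN_MM] = 0.0
    dose = np.clip(dose, 0.0, DOSE_CAP_GY)

    # CT: soft tissue with noise, structure-specific offsets, air outside body
    ct = np.full(shape, HU_AIR)
    ct[body] = HU_BODY + rng.normal(0.0, HU_BODY_SD, size=int(body.sum()))
    ct[masks["PTV55"]] += HU_PTV_OFFSET
    for i, name in enumerate(oar_names):
        ct[masks[name]] += HU_OAR_OFFSET - 2.0 * i

    sp = tuple(spec.spacing_mm)
    return PhantomCase(
        case_id=case_id or f"phantom_{spec.seed:04d}",
        ct=VolumeGrid(ct, sp, "CT_HU"),
        structures=structures,
        dose=VolumeGrid(dose, sp, "DOSE_GY"),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# NIfTI dataset I/O
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.json"


def _affine(spacing_mm: Sequence[float]) -> np.ndarray:
    # arrays are (z, y, x); the affine stores per-axis spacing on its diagonal
    return np.diag(list(spacing_mm) + [1.0])


def _save_nifti(path: Path, values: np.ndarray, spacing_mm: Sequence[float]) -> None:
    img = nib.Nifti1Image(np.asarray(values), _affine(spacing_mm))
    nib.save(img, str(path))


def _load_nifti(path: Path) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    if not path.exists():
        raise FileNotFoundError(f"dataset file missing: {path}")
    img = nib.load(str(path))
    spacing = tuple(float(s) for s in np.diag(img.affine)[:3])
    return np.asarray(img.dataobj, dtype=np.float64), spacing


def write_dataset(cases: Sequence[PhantomCase], directory: str | Path,
                  overwrite: bool = False) -> Dict:
    """Write cases as NIfTI volumes plus a JSON manifest; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / MANIFEST_NAME
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace it")

    entries = []
    spacing = list(cases[0].ct.spacing_mm) if cases else None
    for case in cases:
        cdir = directory / case.case_id
        cdir.mkdir(exist_ok=True)
        _save_nifti(cdir / "ct.nii.gz", case.ct.values, case.ct.spacing_mm)
        _save_nifti(cdir / "dose.nii.gz", case.dose.values, case.dose.spacing_mm)
        mask_paths = {}
        for name, mask in case.structures.masks.items():
            p = cdir / f"mask_{name}.nii.gz"
            _save_nifti(p, mask.astype(np.uint8), case.ct.spacing_mm)
            mask_paths[name] = str(p.relative_to(directory))
        entries.append({
            "id": case.case_id,
            "ct": str((cdir / "ct.nii.gz").relative_to(directory)),
            "dose": str((cdir / "dose.nii.gz").relative_to(directory)),
            "masks": mask_paths,
            "prescription_gy": case.prescription,
            "spec": case.spec.to_json(),
        })
    manifest = {
        "cases": entries,
        "spacing_mm": spacing,
        "created_by": "desire-rt",
        "seed": cases[0].spec.seed if cases else None,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def read_dataset(manifest_path: str | Path) -> List[PhantomCase]:
    """Load cases back from a manifest; masks must be strictly binary and aligned."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest missing: {manifest_path}")
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    cases: List[PhantomCase] = []
    for entry in manifest["cases"]:
        ct_vals, spacing = _load_nifti(root / entry["ct"])
        dose_vals, _ = _load_nifti(root / entry["dose"])
        masks = {}
        for name, rel in entry["masks"].items():
            vals, _ = _load_nifti(root / rel)
            if vals.shape != ct_vals.shape:
                raise ValueError(f"misaligned structure {name!r}: "
                                 f"shape {vals.shape} vs CT {ct_vals.shape}")
            uniq = np.unique(vals)
            if not np.all(np.isin(uniq, (0.0, 1.0))):
                raise ValueError(f"mask {name!r} is not binary (values {uniq[:5]})")
            masks[name] = vals.astype(bool)
        spec = PhantomSpec.from_json(entry["spec"])
        cases.append(PhantomCase(
            case_id=entry["id"],
            ct=VolumeGrid(ct_vals, spacing, "CT_HU"),
            structures=StructureSet(masks, spacing),
            dose=VolumeGrid(dose_vals, spacing, "DOSE_GY"),
            spec=spec,
        ))
    return cases
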