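"""End-to-end run: simulate -> preprocess -> train -> predict -> evaluate.

One :class:`RunConfig` (YAML-serializable) carries every stage's parameters
and a single seed that governs phantom generation, weight initialization and
shuffling.  The config is written to the output directory before any
computation, every stage is deterministic given the seed, and the final
artifacts are a dataset manifest, a model checkpoint, per-case predicted
dose volumes and a combined evaluation CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .dosimetry import GammaParams, evaluate_case
from .grids import DEFAULT_PRESCRIPTION, validate_prescription
from .losses import LossWeights
from .network import ModelConfig, build_model, save_checkpoint
from .phantom import PhantomCase, PhantomSpec, generate_phantom, write_dataset
from .trainer import SchedulerConfig, TrainConfig, predict, train

__all__ = ["RunConfig", "run_pipeline", "make_cases"]

log = logging.getLogger("desire")


@dataclass(frozen=True)
class RunConfig:
    run_id: str = "demo"
    seed: int = 0
    # simulation
    n_cases: int = 2
    grid_shape: Tuple[int, int, int] = (32, 48, 48)
    spacing_mm: Tuple[float, float, float] = (3.0, 2.5, 2.5)
    n_oars: int = 2
    noise_sd_gy: float = 0.5
    prescription_gy: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PRESCRIPTION))
    # model
    base_channels_unet1: int = 8
    rd_growth: int = 4
    dropout_rates: Tuple[float, float, float, float] = (0.1, 0.2, 0.3, 0.4)
    # training
    epochs: int = 50
    batch_size: int = 1
    lr0: float = 3e-4
    scheduler_T0: int = 25
    scheduler_Tmult: int = 2
    scheduler_eta_min: float = 1e-6
    # losses
    alpha: float = 0.5
    beta: float = 0.05
    gamma: float = 0.1
    seg_temperature_gy: float = 1.0
    # evaluation
    gamma_dose_pct: float = 3.0
    gamma_dta_mm: float = 3.0
    gamma_threshold_pct: float = 10.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.prescription_gy:
            raise ValueError("prescription table is required")
        validate_prescription(self.prescription_gy)
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        object.__setattr__(self, "grid_shape", tuple(int(g) for g in self.grid_shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "dropout_rates",
                           tuple(float(r) for r in self.dropout_rates))

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["spacing_mm"] = list(self.spacing_mm)
        d["dropout_rates"] = list(self.dropout_rates)
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- derived sub-configs -------------------------------------------------
    def model_config(self, in_channels: int = 5) -> ModelConfig:
        return ModelConfig(in_channels=in_channels,
                           base_channels_unet1=self.base_channels_unet1,
                           dropout_rates=self.dropout_rates,
                           rd_growth=self.rd_growth, seed=self.seed)

    def train_config(self, checkpoint_dir: Optional[str] = None) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs, batch_size=self.batch_size, lr0=self.lr0,
            scheduler=SchedulerConfig(self.scheduler_T0, self.scheduler_Tmult,
                                      self.scheduler_eta_min),
            loss_weights=LossWeights(self.alpha, self.beta, self.gamma,
                                     self.seg_temperature_gy),
            seed=self.seed, checkpoint_dir=checkpoint_dir)

    def gamma_params(self) -> GammaParams:
        return GammaParams(dose_criterion_pct=self.gamma_dose_pct,
                           dta_mm=self.gamma_dta_mm,
                           threshold_pct=self.gamma_threshold_pct)


def case_seeds(seed: int, n: int) -> List[int]:
    """Deterministic per-case phantom seeds derived from the run seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def make_cases(config: RunConfig) -> List[PhantomCase]:
    cases = []
    for i, s in enumerate(case_seeds(config.seed, config.n_cases)):
        spec = PhantomSpec(grid_shape=config.grid_shape, spacing_mm=config.spacing_mm,
                           n_oars=config.n_oars,
                           prescription_gy=tuple(config.prescription_gy.items()),
                           noise_sd_gy=config.noise_sd_gy, seed=s)
        cases.append(generate_phantom(spec, case_id=f"case_{i:04d}"))
    return cases


def run_pipeline(config: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """Run every stage; returns the combined evaluation table (also on disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")  # serialized before any computation
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    log.info("simulating %d phantom cases", config.n_cases)
    cases = make_cases(config)
    write_dataset(cases, out / "dataset", overwrite=True)

    log.info("training (%d epochs, %d cases)", config.epochs, len(cases))
    model = build_model(config.model_config())
    model, history = train(model, cases, config.train_config(str(out / "checkpoints")))
    history.to_jsonl(out / "history.jsonl")
    save_checkpoint(model, out / "model.npz")
    best_ckpt = out / "checkpoints" / "best.npz"

    log.info("predicting and evaluating (best-loss checkpoint)")
    import nibabel as nib
    from .network import load_checkpoint
    best_model = load_checkpoint(best_ckpt) if best_ckpt.exists() else model
    reports = []
    for case in cases:
        pred = predict(best_model, case)
        nib.save(nib.Nifti1Image(pred.values, np.diag(list(pred.spacing_mm) + [1.0])),
                 str(out / f"pred_{case.case_id}.nii.gz"))
        rep = evaluate_case(pred, case.dose, case.structures, case.prescription,
                            config.gamma_params())
        rep.insert(0, "case", case.case_id)
        reports.append(rep)
    table = pd.concat(reports, ignore_index=True)
    table.to_csv(out / "evaluation.csv", index=False, float_format="%.6f")
    log.info("wrote %s", out / "evaluation.csv")
    return table
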