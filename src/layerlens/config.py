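"""Run configuration: a YAML-backed, schema-validated description of a full
pipeline run.  A single global seed fans out into per-stage sub-seeds (by
stage-name hashing), so each stage is independently reproducible."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .experiments import subseed

__all__ = ["RunConfig", "load_config", "stage_seed", "config_hash"]


class PhantomBlock(BaseModel):
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    layer_fractions: tuple[float, float, float, float, float, float] = (1 / 6,) * 6
    interface_wobble: float = 1.0
    bmode_base: tuple[float, ...] = (1.2, 0.8, 1.5, 0.7, 1.6, 0.9)
    swe_base: tuple[float, ...] = (2.5, 1.8, 3.0, 1.6, 3.2, 2.2)
    speckle_shape: float = Field(4.0, gt=0)
    swe_noise_sd: float = Field(300.0, ge=0)
    signal_layers: tuple[int, ...] = (5,)
    effect_bmode: float | tuple[float, ...] = 0.5
    effect_swe: float | tuple[float, ...] = 2000.0
    interaction_mode: str = "additive"
    n_patients: int = Field(8, ge=1)
    visits_per_patient: int = Field(2, ge=1)
    sites_per_side: int = Field(2, ge=1)
    bmode_reps: int = Field(3, ge=1)
    swe_reps: int = Field(2, ge=1)
    prevalence: float = Field(0.5, gt=0, lt=1)


class TrainingBlock(BaseModel):
    epochs: int = Field(20, ge=1)
    f_min: float = Field(0.2, gt=0, le=1)
    ema_momentum: float = Field(0.9, ge=0, lt=1)
    learning_rate: float = Field(1e-2, gt=0)
    batch_size: int = Field(8, ge=1)
    classifier: str = "linear"
    generator: str | None = "gate"
    n_slabs: int = Field(6, ge=1)
    modalities: tuple[str, ...] = ("bmode", "swe")
    target: str = "mp"


class SaliencyBlock(BaseModel):
    eps: float = Field(1e-8, gt=0)
    ci_method: str = "normal"
    signed_correlation: bool = False


class FaithfulnessBlock(BaseModel):
    rankers: tuple[str, ...] = ("saliency", "random", "volume")


class RunConfig(BaseModel):
    seed: int = 0
    out_dir: str = "layerlens_run"
    cohort_dir: str | None = None  # existing cohort; None -> simulate
    model_dir: str | None = None  # existing model; None -> train
    phantom: PhantomBlock = PhantomBlock()
    training: TrainingBlock = TrainingBlock()
    saliency: SaliencyBlock = SaliencyBlock()
    faithfulness: FaithfulnessBlock = FaithfulnessBlock()
    sanity_replicates: int = Field(3, ge=1)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def stage_seed(config: RunConfig, stage: str) -> int:
    return subseed(config.seed, "stage", stage)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
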