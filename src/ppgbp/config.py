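"""Pipeline configuration: a schema-validated YAML document.

Unknown keys are rejected so that typos in config files fail loudly instead
of silently falling back to defaults.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .model import ExtractorConfig, TrainConfig
from .simulate import SimConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimSection(_Strict):
    n_subjects: int = 200
    cases_per_subject: int = 5
    duration_s: float = 40.0
    fs_ppg: float = 43.0
    fs_force: float = 43.0
    sbp_range: tuple[float, float] = (95.0, 175.0)
    dbp_range: tuple[float, float] = (60.0, 105.0)
    hr_range: tuple[float, float] = (55.0, 100.0)
    force_ramp_exponent: float = 1.0
    pressure_gain: float = 25.0
    max_pressure: float = 215.0
    envelope_width_factor: float = 0.4
    gain_spread: float = 1.5
    offset_sd: float = 0.5
    drift_amplitude: float = 10.0
    noise_sd: float = 3.0
    bp_jitter: float = 2.0

    @field_validator("sbp_range", "dbp_range", "hr_range")
    @classmethod
    def _ordered(cls, v):
        if not v[0] < v[1]:
            raise ValueError(f"range {v} must be (lo, hi) with lo < hi")
        return v

    def to_sim_config(self, seed: int) -> SimConfig:
        return SimConfig(seed=seed, **self.model_dump())


class PreprocessSection(_Strict):
    ppg_band_hz: tuple[float, float] = (0.8, 8.0)
    force_cutoff_hz: float = 0.2
    segment_half_width_s: float = 5.0
    ppg_stream_len: int = 1720
    force_segment_len: int = 215


class TrainSection(_Strict):
    learning_rate: float = 0.005
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 64
    epochs: int = 100
    patience: int = 10
    dropout: float = 0.3
    l2: float = 0.005

    def to_train_config(self, target: str, seed: int, stage: str = "extractor") -> TrainConfig:
        return TrainConfig(
            target=target,
            stage=stage,
            learning_rate=self.learning_rate,
            beta1=self.beta1,
            beta2=self.beta2,
            batch_size=self.batch_size,
            epochs=self.epochs,
            patience=self.patience,
            seed=seed,
        )

    def to_extractor_config(self) -> ExtractorConfig:
        return ExtractorConfig(dropout=self.dropout, l2=self.l2)


class EvalSection(_Strict):
    n_folds: int = 5
    val_fraction: float = 0.2  # of training subjects, for early stopping


class PipelineConfig(_Strict):
    simulate: SimSection = SimSection()
    preprocess: PreprocessSection = PreprocessSection()
    train: TrainSection = TrainSection()
    evaluate: EvalSection = EvalSection()
    targets: tuple[str, ...] = ("SBP", "DBP")
    out_dir: str = "runs"
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML pipeline config (defaults when path is None)."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
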