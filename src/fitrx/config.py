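"""Run configuration: validated, defaults equal the framework's stated
hyperparameters, unknown keys rejected with path-qualified messages."""

from __future__ import annotations

import hashlib
import json
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class CohortSection(_Strict):
    n: int = Field(default=500, ge=4)
    class_proportions: tuple[float, float, float, float] = (0.053, 0.745, 0.190, 0.012)

    @field_validator("class_proportions")
    @classmethod
    def _sum_to_one(cls, v):
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        return v


class SmoteSection(_Strict):
    k: int = Field(default=5, ge=1)


class NoiseSection(_Strict):
    sigma: float = Field(default=0.1, ge=0.0)


class CVSection(_Strict):
    folds: int = Field(default=5, ge=2)


class ExtractorSection(_Strict):
    conv_filters: tuple[int, ...] = (64, 128, 256)
    kernel: int = Field(default=5, ge=1)
    stride: int = Field(default=2, ge=1)
    heads: int = Field(default=8, ge=1)
    attn_dropout: float = Field(default=0.3, ge=0.0, lt=1.0)
    lambda_attn: float = Field(default=0.1, ge=0.0)
    metric_weights: tuple[float, float, float, float] = (0.4, 0.2, 0.2, 0.2)
    lr: float = Field(default=0.001, gt=0.0)
    l2: float = Field(default=1e-4, ge=0.0)
    hidden_noise: float = Field(default=0.05, ge=0.0)
    patience: int = Field(default=10, ge=1)
    max_epochs: int = Field(default=30, ge=1)
    batch_size: int = Field(default=128, ge=1)

    @field_validator("metric_weights")
    @classmethod
    def _weights_sum(cls, v):
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("metric_weights must sum to 1")
        return v


class GBMSection(_Strict):
    n_trees: int = Field(default=200, ge=1)
    learning_rate: float = Field(default=0.1, gt=0.0)
    num_leaves: int = Field(default=31, ge=2)
    lambda_l1: float = Field(default=1.2, ge=0.0)
    lambda_l2: float = Field(default=0.8, ge=0.0)
    one_vs_rest: bool = False


class PrescriptionSection(_Strict):
    frbi_threshold: float = Field(default=1.2, gt=0.0)
    deload_fraction: float = Field(default=0.175, ge=0.15, le=0.20)
    deload_days: int = Field(default=4, ge=3, le=5)
    improvement_threshold: float = Field(default=0.02, ge=0.0)
    volume_increment: float = Field(default=0.075, ge=0.05, le=0.10)
    emphasis_load: float = Field(default=1.2, ge=1.0)


class RunConfig(_Strict):
    seed: int = 42
    out_dir: str = "runs"
    verbosity: int = Field(default=1, ge=0, le=2)
    cohort: CohortSection = CohortSection()
    smote: SmoteSection = SmoteSection()
    noise: NoiseSection = NoiseSection()
    cv: CVSection = CVSection()
    extractor: ExtractorSection = ExtractorSection()
    gbm: GBMSection = GBMSection()
    prescription: PrescriptionSection = PrescriptionSection()

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


def validate_config(raw: dict[str, Any] | None) -> RunConfig:
    """Build a RunConfig from a raw mapping; empty input yields full defaults."""
    return RunConfig.model_validate(raw or {})


def load_config(path: str | None = None, overrides: list[str] | None = None) -> RunConfig:
    """Load YAML config (optional) and apply `section.key=value` overrides."""
    raw: dict[str, Any] = {}
    if path:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    for item in overrides or []:
        key, _, value = item.partition("=")
        if not _:
            raise ValueError(f"override {item!r} must look like section.key=value")
        node = raw
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = yaml.safe_load(value)
    return validate_config(raw)


def serialize_config(cfg: RunConfig) -> str:
    return json.dumps(cfg.model_dump(), sort_keys=True, indent=2, default=list)
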