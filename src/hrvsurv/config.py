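"""Pipeline configuration: a validated, hashable YAML/JSON-backed schema."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .exceptions import SchemaError
from .spectral import SpectrumConfig

__all__ = ["ModelConfig", "EvaluationConfig", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class ModelConfig:
    """Model-stage settings.

    ``candidates`` fixes the stepwise candidate order (ties on p-values are
    broken by this order); ``hrv_index`` is the continuous index submitted to
    cutpoint discovery, adjusted for ``adjust_terms``; ``cutpoint`` overrides
    the discovered value when set.
    """

    candidates: tuple[str, ...] = (
        "cognitive_impairment", "ascites", "jaundice", "edema", "ecog_34",
    )
    hrv_index: str = "ln_hfp"
    adjust_terms: tuple[str, ...] = ("ecog_34",)
    cutpoint: float | None = None
    sle: float = 0.15
    sls: float = 0.15
    prune_alpha: float = 0.05


@dataclass(frozen=True)
class EvaluationConfig:
    ci_method: str = "wilson"


@dataclass(frozen=True)
class PipelineConfig:
    spectrum: SpectrumConfig = field(default_factory=SpectrumConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    simulate_n: int = 138
    seed: int = 0
    output_dir: str = "hrvsurv_output"

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build(cls, payload: dict, context: str):
    if not isinstance(payload, dict):
        raise SchemaError(f"{context}: expected a mapping, got {type(payload).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = sorted(set(payload) - set(known))
    if unknown:
        raise SchemaError(f"{context}: unknown key(s): {', '.join(unknown)}")
    kwargs = {}
    for key, value in payload.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{context}: {exc}") from exc


def load_config(path) -> PipelineConfig:
    """Load a pipeline configuration from YAML (or JSON) and validate it."""
    path = Path(path)
    payload = yaml.safe_load(path.read_text()) or {}
    if not isinstance(payload, dict):
        raise SchemaError(f"{path}: top level must be a mapping")
    nested = {
        "spectrum": SpectrumConfig,
        "model": ModelConfig,
        "evaluation": EvaluationConfig,
    }
    kwargs = {}
    for key, value in payload.items():
        if key in nested:
            kwargs[key] = _build(nested[key], value, f"{path}:{key}")
        elif key in {f.name for f in fields(PipelineConfig)}:
            kwargs[key] = value
        else:
            raise SchemaError(f"{path}: unknown key {key!r}")
    try:
        return PipelineConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc
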