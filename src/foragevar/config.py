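"""Pipeline configuration: defaults, YAML loading, and an audit hash."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .data_io import ELEMENTS, RATIOS, LIFE_STAGES
from .decomposition import DEFAULT_LOG10_TARGETS
from .errors import ValidationError
from .trend_models import DF_RULES


@dataclass
class PipelineConfig:
    """Everything :func:`foragevar.pipeline.run_all` needs.

    Either the three input paths or a scenario ``preset`` name must be
    given. Thresholds default to the conventions used throughout the
    package: 15% SS share for a contributing component, p < 0.1 for a
    gradient-related site trend, p < 0.05 for a within-species trend,
    a 5-fold within-species spread for outlier species, and 100% / 20%
    cutoffs for the sufficient / severely-limiting grades.
    """

    survey: str | None = None
    chemistry: str | None = None
    environment: str | None = None
    preset: str | None = None
    seed: int = 0
    output_dir: str = "foragevar_out"

    elements: tuple[str, ...] = ELEMENTS
    ratios: tuple[str, ...] = RATIOS
    log10_targets: tuple[str, ...] = DEFAULT_LOG10_TARGETS

    theta_contrib: float = 0.15
    trend_alpha: float = 0.1
    mixed_alpha: float = 0.05
    theta_outlier: float = 5.0
    sufficient_cut: float = 1.0
    severe_cut: float = 0.2
    life_stage: str = "lactating"
    df_rule: str = "residual"
    min_sites_within: int = 3
    n_plots: int = 21
    n_layers: int = 4

    def validate(self) -> None:
        if self.preset is None and not (self.survey and self.chemistry and self.environment):
            raise ValidationError("give either a preset or all three input paths")
        if not set(self.elements) <= set(ELEMENTS):
            raise ValidationError(f"elements must be a subset of {ELEMENTS}")
        if not set(self.ratios) <= set(RATIOS):
            raise ValidationError(f"ratios must be a subset of {RATIOS}")
        for name in ("theta_contrib", "trend_alpha", "mixed_alpha",
                     "sufficient_cut", "severe_cut"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.theta_outlier <= 1:
            raise ValidationError("theta_outlier must exceed 1")
        if self.life_stage not in LIFE_STAGES:
            raise ValidationError(f"life_stage must be one of {LIFE_STAGES}")
        if self.df_rule not in DF_RULES:
            raise ValidationError(f"df_rule must be one of {DF_RULES}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("elements", "ratios", "log10_targets"):
            d[key] = list(d[key])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s) {sorted(unknown)}")
        for key in ("elements", "ratios", "log10_targets"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg
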