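"""Structured configuration for the full pipeline, YAML-loadable.

Sections map one-to-one onto the stage configs: ``detection`` (MALC),
``scoring`` (Kalman noises, score-test threshold, likelihood densities,
score weights), ``tracker`` (tree depth, termination, gate), ``pruning``
(stage toggles, loop rule), ``selection`` (K, C_IN, N_T, association mode)
and ``pipeline`` (batch length / overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .hypotheses import TrackerConfig
from .malc import DetectionConfig
from .motion import ScoringConfig
from .pruning import PruningConfig
from .selection import SelectionConfig

__all__ = ["BatchConfig", "PipelineConfig", "load_config"]


@dataclass
class BatchConfig:
    """Sliding-window batching: selection runs over ``batch`` frames and
    commits the front ``batch - overlap`` of them."""

    batch: int = 40
    overlap: int = 20


@dataclass
class PipelineConfig:
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    pruning: PruningConfig = field(default_factory=PruningConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    pipeline: BatchConfig = field(default_factory=BatchConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls()
        for f in fields(cls):
            section = data.get(f.name)
            if section is None:
                continue
            target = getattr(cfg, f.name)
            valid = {fld.name for fld in fields(target)}
            unknown = set(section) - valid
            if unknown:
                raise ValueError(f"unknown keys in '{f.name}': {sorted(unknown)}")
            for key, value in section.items():
                setattr(target, key, value)
        return cfg


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)
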