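"""YAML configuration loading for the pipeline and CLI.

A config file carries up to four blocks::

    consensus:
      k_min: 2
      k_max: 8
      n_runs: 50
      subsample_fraction: 0.8
      seed: 0
      identity_epsilon: 1.0e-6
      statistic: pac        # or delta-area
    tracking:
      method: optimal      # or greedy
      theta: 0.1
      palette: Set1
    ordering:
      block_size: 10
      n_sweeps: 4
      objective: weighted-link-distance
    views:
      width: 1200
      wmin: 120
      C: 1.0

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .communities import ConsensusParams
from .ordering import OrderingConfig


@dataclass
class TrackingConfig:
    method: str = "optimal"
    theta: float = 0.1
    palette: str = "Set1"

    def __post_init__(self) -> None:
        if self.method not in ("greedy", "optimal"):
            raise ValueError("tracking method must be 'greedy' or 'optimal'")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")


@dataclass
class ViewsConfig:
    width: float = 1200.0
    wmin: float = 120.0
    C: float = 1.0


@dataclass
class PipelineConfig:
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    ordering: OrderingConfig = field(default_factory=OrderingConfig)
    views: ViewsConfig = field(default_factory=ViewsConfig)


def _build(cls, block: dict[str, Any], name: str):
    valid = set(cls.__dataclass_fields__)
    unknown = set(block) - valid
    if unknown:
        raise ValueError(f"unknown key(s) in '{name}' block: {sorted(unknown)}")
    return cls(**block)


def load_config(path: Optional[str | Path] = None) -> PipelineConfig:
    """Load a pipeline configuration; missing blocks take defaults."""
    if path is None:
        return PipelineConfig()
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(doc) - {"consensus", "tracking", "ordering", "views"}
    if unknown:
        raise ValueError(f"unknown config block(s): {sorted(unknown)}")
    return PipelineConfig(
        consensus=_build(ConsensusParams, doc.get("consensus", {}), "consensus"),
        tracking=_build(TrackingConfig, doc.get("tracking", {}), "tracking"),
        ordering=_build(OrderingConfig, doc.get("ordering", {}), "ordering"),
        views=_build(ViewsConfig, doc.get("views", {}), "views"),
    )
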