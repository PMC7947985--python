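"""Load the threshold/weight configuration (YAML key-value tree).

The shipped default reproduces the published indicator threshold ranges and
metadata weights; analysts can supply an alternative file for sensitivity
analyses without code changes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .burden import ThresholdRow, ThresholdTable
from .weighting import WeightConfig


@dataclass(frozen=True)
class ScoringConfig:
    thresholds: ThresholdTable
    weights: WeightConfig
    sha256: str


def _default_text() -> str:
    return (
        resources.files("nutrigap").joinpath("data/default_config.yaml").read_text()
    )


def load_config(path: Optional[str | Path] = None) -> ScoringConfig:
    """Load a scoring configuration; ``None`` loads the shipped default."""
    text = Path(path).read_text() if path is not None else _default_text()
    raw = yaml.safe_load(text)
    rows = tuple(ThresholdRow(**r) for r in raw["thresholds"])
    thresholds = ThresholdTable(rows=rows)
    weights = WeightConfig.from_mapping(raw["weights"])
    digest = hashlib.sha256(text.encode()).hexdigest()
    return ScoringConfig(thresholds=thresholds, weights=weights, sha256=digest)


def default_config() -> ScoringConfig:
    return load_config(None)
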