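"""Run configuration: a single YAML file tying together display, detector and
operator settings, fixture selection, seeds and the output directory.

All randomness in a run flows from the single ``seed`` via named substreams
(protocol, operator, dataset), so identical configurations reproduce
identical outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .displays import DisplayConfig
from .simulate import OperatorModel

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    display: DisplayConfig = field(default_factory=DisplayConfig)
    operator: OperatorModel = field(default_factory=OperatorModel)
    hold_duration: float = 2.0
    fixture: str = "spine"
    fixture_path: str | None = None
    seed: int = 0
    out_dir: str = "tminav_out"

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if self.fixture_path is not None and not Path(self.fixture_path).exists():
            raise ValueError(f"fixture file does not exist: {self.fixture_path}")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a RunConfig from YAML (or defaults), applying keyword overrides."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    display = DisplayConfig(**data.pop("display", {}))
    operator = OperatorModel(**data.pop("operator", {}))
    return RunConfig(display=display, operator=operator, **data)
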