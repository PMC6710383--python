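"""Run configuration: serializable descriptions of reproducible runs."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import ModelParams

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything needed to reproduce an experiment run.

    ``sequences`` selects the stimulus set: ``"all-unimodal"``,
    ``"all-crossmodal"``, or an explicit list of compact sequence
    strings.  ``item_range`` is ``[start, stop]`` on the tested-item
    axis (half-open, like Python ranges).
    """

    experiment: str = "simulate"
    visual_params: ModelParams = field(default_factory=ModelParams.visual)
    auditory_params: ModelParams = field(default_factory=ModelParams.auditory)
    sequences: object = "all-unimodal"
    item_range: tuple = (6, 26)
    n_runs: int = 10
    base_seed: int = 0
    grid_size: int = 20
    geometry: str = "disjoint"
    repetitions: int = 20
    output_dir: str = "oscseq-out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["item_range"] = list(self.item_range)
        if isinstance(self.sequences, (list, tuple)):
            d["sequences"] = list(self.sequences)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("visual_params", "auditory_params"):
            if key in d and isinstance(d[key], dict):
                d[key] = ModelParams(**d[key])
        if "item_range" in d:
            d["item_range"] = tuple(d["item_range"])
        return cls(**d)


def save_config(config: RunConfig, path) -> None:
    """Write a config as YAML (or JSON if the suffix says so)."""
    path = Path(path)
    text = (json.dumps(config.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(config.to_dict(), sort_keys=False))
    path.write_text(text)


def load_config(path) -> RunConfig:
    """Read a YAML or JSON config; round-trips with :func:`save_config`."""
    text = Path(path).read_text()
    data = (json.loads(text) if str(path).endswith(".json")
            else yaml.safe_load(text))
    return RunConfig.from_dict(data)
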