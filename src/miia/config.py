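"""Run configuration: validated settings shared by the CLI commands."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .binary import FORMS, Pair
from .data import AGGREGATION_MODES
from .exceptions import ConfigError
from .replicates import NoiseSpec
from .sensitivity import ParameterAssignment, parse_pair

CONFIG_FORMS = FORMS + ("both",)


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run.

    ``assignments`` uses the ``affected<-influencer`` pair syntax; the sweep
    grid is given as ``{"start": -5, "stop": 5, "num": 41}``.
    """

    detection_limit: float = 0.0
    form: str = "scaled"
    aggregation: str = "mean"
    assignments: Dict[str, float] = field(default_factory=dict)
    sweep_grid: Dict[str, float] = field(
        default_factory=lambda: {"start": -5.0, "stop": 5.0, "num": 41}
    )
    scenarios: List[Dict] = field(default_factory=list)
    noise: Dict[str, float] = field(
        default_factory=lambda: {"sigma": 0.05, "seed": 0, "n_replicates": 3}
    )
    seed: int = 0
    out_dir: str = "."
    strict: bool = False

    def __post_init__(self):
        if self.detection_limit < 0:
            raise ConfigError("detection_limit must be >= 0")
        if self.form not in CONFIG_FORMS:
            raise ConfigError(f"form must be one of {CONFIG_FORMS}, got {self.form!r}")
        if self.aggregation not in AGGREGATION_MODES:
            raise ConfigError(
                f"aggregation must be one of {AGGREGATION_MODES}, got {self.aggregation!r}"
            )
        unknown = set(self.sweep_grid) - {"start", "stop", "num"}
        if unknown:
            raise ConfigError(f"unknown sweep_grid keys: {sorted(unknown)}")
        if int(self.sweep_grid.get("num", 41)) < 1:
            raise ConfigError("sweep_grid.num must be >= 1")
        unknown = set(self.noise) - {"sigma", "seed", "n_replicates"}
        if unknown:
            raise ConfigError(f"unknown noise keys: {sorted(unknown)}")
        # eagerly validate pair syntax and scenario structure
        self.parsed_assignments()
        self.scenario_list()

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(data))

    @classmethod
    def load(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        try:
            if str(path).endswith(".json"):
                data = json.loads(text)
            else:
                data = yaml.safe_load(text)
        except (yaml.YAMLError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from None
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
        return cls.from_dict(data)

    # -- derived objects ------------------------------------------------------
    def parsed_assignments(self) -> Dict[Pair, float]:
        return {parse_pair(str(k)): float(v) for k, v in self.assignments.items()}

    def grid(self) -> np.ndarray:
        g = self.sweep_grid
        return np.linspace(
            float(g.get("start", -5.0)), float(g.get("stop", 5.0)), int(g.get("num", 41))
        )

    def noise_spec(self) -> NoiseSpec:
        n = self.noise
        return NoiseSpec(
            sigma=float(n.get("sigma", 0.05)),
            seed=int(n.get("seed", self.seed)),
            n_replicates=int(n.get("n_replicates", 3)),
        )

    def scenario_list(self) -> List[ParameterAssignment]:
        return [ParameterAssignment.from_dict(s) for s in self.scenarios]

    def forms(self) -> Tuple[str, ...]:
        return FORMS if self.form == "both" else (self.form,)
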