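"""Run configuration: serializable bundle of pendulum, geometry, observer and fit options."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .kinematics import PendulumParams
from .observer import ExperimentDesign, ObserverModel
from .stimulus import DisplayGeometry

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run from a single file."""

    pendulum: PendulumParams = field(default_factory=PendulumParams)
    geometry: DisplayGeometry = field(default_factory=DisplayGeometry)
    observer: ObserverModel = field(default_factory=ObserverModel)
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    seed: int = 0
    orientations: tuple[float, ...] = (0.0, 90.0, 180.0)
    reverse_method: str = "reflect"
    sim_mode: str = "procedural"
    reference_level: str | None = None
    random_structure: str = "diagonal"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"]["conditions"] = list(self.design.conditions)
        d["design"]["starting_set"] = list(self.design.starting_set)
        d["orientations"] = list(self.orientations)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Short stable hash of the resolved configuration (names run directories)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        if "pendulum" in d:
            kwargs["pendulum"] = PendulumParams(**d["pendulum"])
        if "geometry" in d:
            g = d["geometry"]
            kwargs["geometry"] = DisplayGeometry(**g)
        if "observer" in d:
            kwargs["observer"] = ObserverModel(**d["observer"])
        if "design" in d:
            dd = dict(d["design"])
            dd["conditions"] = tuple(str(c) for c in dd.get("conditions", ()))
            dd["starting_set"] = tuple(dd.get("starting_set", (2, 6, 10, 14, 18)))
            kwargs["design"] = ExperimentDesign(**dd)
        for key in (
            "seed",
            "reverse_method",
            "sim_mode",
            "reference_level",
            "random_structure",
        ):
            if key in d:
                kwargs[key] = d[key]
        if "orientations" in d:
            kwargs["orientations"] = tuple(float(o) for o in d["orientations"])
        return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML (JSON is a YAML subset and loads too)."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig.from_dict(data)
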