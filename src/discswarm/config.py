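"""Run configuration: every knob of the pipeline in one YAML/JSON-able record."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

from .swarm import SwarmConfig

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration (polar grid + swarm + evaluation).

    ``rmin``/``rmax``/``delta_theta`` of None mean "derive from the image
    size / subgroup count" (30% and 70% of half the width; an angular step
    whose column count is a multiple of the subgroup count).
    """

    # polar exploration area
    image_size: int = 256
    center: tuple[float, float] | str = "auto"
    rmin: float | None = None
    rmax: float | None = None
    delta_r: float = 1.0
    delta_theta: float | None = None
    smoothing_sigma: float = 2.0
    # swarm
    n_subgroups: int = 50
    n_particles: int = 30
    iterations: int = 100
    inertia: str = "constant"
    omega: float = 0.8
    omega_max: float = 0.9
    omega_min: float = 0.4
    chaotic_z_coef: float = 0.5
    chaotic_rand_coef: float = 0.5
    cp: float = 1.7
    cg: float = 1.7
    ca: float = 0.3
    velocity_clamp: float = 0.2
    radius_only: bool = False
    fit_method: str = "spline"
    # evaluation
    metric_mode: str = "fractional"
    truth_threshold: float = 0.75
    # reproducibility
    seed: int = 0

    def swarm_config(self) -> SwarmConfig:
        names = {f.name for f in fields(SwarmConfig)}
        return SwarmConfig(**{k: v for k, v in asdict(self).items() if k in names})

    def polar_kwargs(self) -> dict:
        center = self.center
        if not isinstance(center, str):
            center = (float(center[0]), float(center[1]))
        return dict(
            center=center,
            rmin=self.rmin,
            rmax=self.rmax,
            delta_r=self.delta_r,
            delta_theta=self.delta_theta,
            n_subgroups=self.n_subgroups,
            sigma=self.smoothing_sigma,
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        if not isinstance(d["center"], str):
            d["center"] = list(d["center"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "center" in data and not isinstance(data["center"], str):
            data["center"] = tuple(data["center"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))
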