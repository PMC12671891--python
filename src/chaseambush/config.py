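"""Configuration loading, sweep plans and desk-scale fixture profiles."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .abm import S_GRID, AgentTrait, WorldConfig

__all__ = ["SweepPlan", "load_config", "make_fixture", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SweepPlan:
    """A full sweep: world constants plus the trait and condition grids."""

    algorithm: str
    world: WorldConfig
    sense_grid: tuple[float, ...]  # d values (sensory) or K values (non-sensory)
    S_grid: tuple[float, ...]
    c_b_grid: tuple[float, ...]
    r_grid: tuple[float, ...]
    repeats: int
    master_seed: int

    def __post_init__(self) -> None:
        if self.algorithm not in ("sensory", "non_sensory"):
            raise ConfigError(f"unknown algorithm {self.algorithm!r}")
        for name in ("sense_grid", "S_grid", "c_b_grid", "r_grid"):
            if len(getattr(self, name)) == 0:
                raise ConfigError(f"{name} must be non-empty")
        for s in self.S_grid:
            if not -1.0 <= s <= 1.0:
                raise ConfigError(f"S value {s} outside [-1, 1]")
        if self.repeats < 1:
            raise ConfigError("repeats must be >= 1")

    def conditions(self):
        """All (sense_s, sense_w, c_b, r) combinations, with a stable index."""
        idx = 0
        for c_b in self.c_b_grid:
            for r in self.r_grid:
                for ts in self.sense_grid:
                    for tw in self.sense_grid:
                        yield idx, {"algorithm": self.algorithm, "sense_s": ts, "sense_w": tw, "c_b": c_b, "r": r}
                        idx += 1

    def traits_for(self, cond: dict) -> tuple[AgentTrait, AgentTrait]:
        if self.algorithm == "sensory":
            prey = AgentTrait(role="prey", algorithm="sensory", S=0.0, d=cond["sense_s"], f=self.world.f)
            pred = AgentTrait(role="predator", algorithm="sensory", S=0.0, d=cond["sense_w"], f=self.world.f)
        else:
            prey = AgentTrait(role="prey", algorithm="non_sensory", S=0.0, K=cond["sense_s"])
            pred = AgentTrait(role="predator", algorithm="non_sensory", S=0.0, K=cond["sense_w"])
        return prey, pred

    def world_for(self, cond: dict) -> WorldConfig:
        return dataclasses.replace(self.world, c_b=cond["c_b"], r=cond["r"])


_WORLD_KEYS = {f.name for f in dataclasses.fields(WorldConfig)}
_PLAN_KEYS = {
    "algorithm",
    "sense_grid",
    "S_grid",
    "c_b_grid",
    "r_grid",
    "repeats",
    "master_seed",
    "world",
}


def load_config(path) -> SweepPlan:
    """Read and validate a YAML sweep plan; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - _PLAN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("algorithm", "sense_grid", "S_grid", "c_b_grid", "r_grid", "repeats", "master_seed"):
        if key not in raw:
            raise ConfigError(f"missing required config key: {key!r}")
    world_raw = raw.get("world", {}) or {}
    unknown_w = set(world_raw) - _WORLD_KEYS
    if unknown_w:
        raise ConfigError(f"unknown world keys: {sorted(unknown_w)}")
    if "window" in world_raw:
        world_raw["window"] = tuple(world_raw["window"])
    try:
        world = WorldConfig(**world_raw)
        plan = SweepPlan(
            algorithm=raw["algorithm"],
            world=world,
            sense_grid=tuple(float(v) for v in raw["sense_grid"]),
            S_grid=tuple(float(v) for v in raw["S_grid"]),
            c_b_grid=tuple(float(v) for v in raw["c_b_grid"]),
            r_grid=tuple(float(v) for v in raw["r_grid"]),
            repeats=int(raw["repeats"]),
            master_seed=int(raw["master_seed"]),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return plan


def make_fixture(profile: str) -> SweepPlan:
    """Desk-scale stand-in configurations.

    * ``fast`` -- a small world (25x25 patches, 80 sheep, 20 wolves, 800-tick
      horizon, 3x3 S grid) that sustains predator-prey coexistence while the
      full sweep -> matrix -> equilibria pipeline completes in seconds;
    * ``grid_only`` -- the exact single-pair lattice computation (no IBM);
    * ``full_paper`` -- the complete study grids: 4x4 detection combinations,
      the 11-point S grid, all (c_b, r) conditions, 6 repeats at an 11,000
      tick horizon.  This is a multi-hour computation on one CPU.
    """
    if profile == "fast":
        world = WorldConfig(
            world_width=25,
            world_height=25,
            grass_regrowth_time=30,
            initial_sheep=80,
            initial_wolves=20,
            sheep_gain_from_food=4.0,
            wolf_gain_from_food=20.0,
            sheep_reproduce=4.0,
            r=3.6,
            c_e=0.5,
            c_b=0.02,
            c_m=0.5,
            horizon=800,
            window=(500, 800),
        )
        return SweepPlan(
            algorithm="sensory",
            world=world,
            sense_grid=(0.0, 0.2),
            S_grid=(-1.0, 0.0, 1.0),
            c_b_grid=(0.0, 0.02),
            r_grid=(3.2, 4.0),
            repeats=1,
            master_seed=0,
        )
    if profile == "grid_only":
        world = WorldConfig()
        return SweepPlan(
            algorithm="sensory",
            world=world,
            sense_grid=(0.0, 0.1, 0.2),
            S_grid=(-1.0, 0.0, 1.0),
            c_b_grid=(0.0,),
            r_grid=(3.6,),
            repeats=1,
            master_seed=0,
        )
    if profile == "full_paper":
        world = WorldConfig()
        return SweepPlan(
            algorithm="sensory",
            world=world,
            sense_grid=(0.0, 0.1, 0.2, 0.3),
            S_grid=tuple(float(s) for s in S_GRID),
            c_b_grid=(0.0, 0.001, 0.02, 0.04),
            r_grid=(3.2, 3.6, 4.0),
            repeats=6,
            master_seed=0,
        )
    raise ConfigError(f"unknown fixture profile {profile!r}")
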