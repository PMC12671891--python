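"""Continuous-space torus predator-prey individual-based model.

A re-implementation of the classic wolf-sheep-predation ecology extended
with the two behavioral algorithms studied here:

* **sensory-motor** -- an agent moving at default speed 1 switches to speed
  ``1 + S`` on ticks where an opponent lies within its detection distance
  ``D = d * f`` (no directional information is used, only presence);
* **non-sensory motor** -- the agent switches to ``1 + S`` with a fixed
  per-tick probability ``K``, with no sensing at all.

Agents occupy real-valued coordinates on a torus of integer patches.  Sheep
graze (a green patch feeds one sheep and turns brown until it regrows),
wolves eat one co-located sheep per tick, both reproduce by energy-halving
splits and die when their energy is exhausted.  Every tick costs

``c_e + (d + |S|) * c_b + speed * c_m``

where the speed factor is ``1 + S`` on speed-change ticks and 1 otherwise,
and ``d`` is replaced by ``K`` under the non-sensory algorithm.  Encounters
(predation events per tick, ``E``) together with the post-interaction
population counts ``N_w`` and ``N_s`` are the raw measurements from which
payoffs are built downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "WorldConfig",
    "Mixture",
    "AgentTrait",
    "TickRecord",
    "World",
    "RunResult",
    "sense",
    "choose_speed",
    "move",
    "tick_cost",
    "run",
]

S_GRID = tuple(np.round(np.arange(-1.0, 1.01, 0.2), 1))  # 11 speed deltas


@dataclass(frozen=True)
class WorldConfig:
    """World constants of the torus model.

    Defaults mirror the standard wolf-sheep-predation setup (51x51 patches,
    100 sheep, 50 wolves, gains 4/20, 30-tick grass regrowth, 4% sheep
    reproduction) with basal and movement costs ``c_e = c_m = 0.5`` so that
    an unchanged tick costs one energy unit at zero behavioral cost.
    ``r`` is the predator reproduction coefficient in percent per tick.
    """

    world_width: int = 51
    world_height: int = 51
    grass_regrowth_time: int = 30
    initial_sheep: int = 100
    initial_wolves: int = 50
    sheep_gain_from_food: float = 4.0
    wolf_gain_from_food: float = 20.0
    sheep_reproduce: float = 4.0
    r: float = 3.6
    c_e: float = 0.5
    c_b: float = 0.0
    c_m: float = 0.5
    f: float = 10.0
    horizon: int = 11000
    window: tuple[int, int] = (10000, 11000)

    def __post_init__(self) -> None:
        if min(self.world_width, self.world_height) <= 0:
            raise ValueError("world extents must be positive")
        if self.grass_regrowth_time <= 0:
            raise ValueError("grass_regrowth_time must be positive")
        if self.f <= 0:
            raise ValueError("sensitivity factor f must be positive")
        for name in ("sheep_reproduce", "r"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} is a percent probability, got {v}")
        lo, hi = self.window
        if not (0 <= lo < hi <= self.horizon):
            raise ValueError("window must be a non-empty slice of [0, horizon]")


@dataclass(frozen=True)
class Mixture:
    """A probability distribution over speed deltas (a mixed strategy)."""

    support: tuple[float, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if len(self.support) != len(p) or len(p) == 0:
            raise ValueError("support and probs must be equal-length and non-empty")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probs must be a probability vector")

    @property
    def is_degenerate(self) -> bool:
        return len(self.support) == 1

    @property
    def mean_abs(self) -> float:
        return float(np.dot(np.abs(self.support), self.probs))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(np.asarray(self.support, dtype=float), size=n, p=self.probs)


@dataclass(frozen=True)
class AgentTrait:
    """Heritable behavior of one role: algorithm, sensing and speed change.

    ``S`` may be a scalar speed delta or a :class:`Mixture`; mixtures are
    realized per triggered event by default (a fresh draw on each tick where
    the speed change fires), or fixed per agent at birth when
    ``sampling_rule="per_birth"``.
    """

    role: Literal["predator", "prey"]
    algorithm: Literal["sensory", "non_sensory"]
    S: float | Mixture
    d: float | None = None
    K: float | None = None
    f: float = 10.0
    sampling_rule: Literal["per_event", "per_birth"] = "per_event"

    def __post_init__(self) -> None:
        if self.algorithm == "sensory":
            if self.d is None or self.K is not None:
                raise ValueError("sensory traits take d (and no K)")
            if self.d < 0:
                raise ValueError("sensory investment d must be non-negative")
        elif self.algorithm == "non_sensory":
            if self.K is None or self.d is not None:
                raise ValueError("non-sensory traits take K (and no d)")
            if not 0 <= self.K <= 1:
                raise ValueError("K must be a probability")
        else:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        for s in self.s_support:
            if not -1.0 <= s <= 1.0:
                raise ValueError(f"speed delta {s} outside [-1, 1]")

    @property
    def D(self) -> float:
        """Detection distance in patch units (sensory algorithm only)."""
        return 0.0 if self.d is None else self.d * self.f

    @property
    def s_support(self) -> tuple[float, ...]:
        return self.S.support if isinstance(self.S, Mixture) else (float(self.S),)

    @property
    def cost_trait(self) -> float:
        """The trait entering the behavioral cost term: d or K."""
        return self.d if self.algorithm == "sensory" else self.K

    @property
    def mean_abs_S(self) -> float:
        return self.S.mean_abs if isinstance(self.S, Mixture) else abs(float(self.S))


@dataclass(frozen=True)
class TickRecord:
    """Post-interaction measurements of one tick."""

    t: int
    E: int
    N_w: int
    N_s: int

    def __post_init__(self) -> None:
        if min(self.E, self.N_w, self.N_s) < 0:
            raise ValueError("tick counts must be non-negative")


class _Population:
    """Flat arrays for one role; dead agents are compacted away each phase."""

    __slots__ = ("x", "y", "heading", "energy", "ids", "s_birth")

    def __init__(self, x, y, heading, energy, ids, s_birth):
        self.x = x
        self.y = y
        self.heading = heading
        self.energy = energy
        self.ids = ids
        self.s_birth = s_birth  # per-agent S for per-birth mixture sampling

    @property
    def n(self) -> int:
        return len(self.x)

    def keep(self, mask: np.ndarray) -> None:
        for name in self.__slots__:
            setattr(self, name, getattr(self, name)[mask])

    def append(self, other: "_Population") -> None:
        for name in self.__slots__:
            setattr(self, name, np.concatenate([getattr(self, name), getattr(other, name)]))


def _torus_delta(a: np.ndarray, b: np.ndarray, extent: float) -> np.ndarray:
    d = np.abs(a - b)
    return np.minimum(d, extent - d)


def sense(
    x: np.ndarray,
    y: np.ndarray,
    opp_x: np.ndarray,
    opp_y: np.ndarray,
    D: float,
    width: float,
    height: float,
) -> np.ndarray:
    """True where any opponent lies within Euclidean distance D (torus wrap).

    ``D = 0`` never detects; an empty opponent roster never detects.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if D <= 0 or len(opp_x) == 0:
        return np.zeros(len(x), dtype=bool)
    dx = _torus_delta(x[:, None], np.asarray(opp_x)[None, :], width)
    dy = _torus_delta(y[:, None], np.asarray(opp_y)[None, :], height)
    return ((dx * dx + dy * dy) <= D * D).any(axis=1)


def choose_speed(
    trait: AgentTrait,
    detected: np.ndarray,
    rng: np.random.Generator,
    s_birth: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-agent (speed, changed flag, S used) for one tick.

    Sensory agents change speed exactly on detection ticks; non-sensory
    agents change with probability K regardless of ``detected``.  The speed
    is clamped at zero (``S = -1`` means a full stop; there is no backward
    motion).
    """
    detected = np.atleast_1d(np.asarray(detected, dtype=bool))
    n = len(detected)
    if trait.algorithm == "sensory":
        changed = detected.copy()
    else:
        changed = rng.random(n) < trait.K
    if isinstance(trait.S, Mixture):
        if trait.sampling_rule == "per_birth":
            if s_birth is None:
                raise ValueError("per_birth sampling requires per-agent S values")
            s_used = np.asarray(s_birth, dtype=float).copy()
        else:
            s_used = np.zeros(n)
            k = int(changed.sum())
            if k:
                s_used[changed] = trait.S.sample(rng, k)
    else:
        s_used = np.full(n, float(trait.S))
    speed = np.where(changed, np.maximum(0.0, 1.0 + s_used), 1.0)
    return speed, changed, s_used


def move(
    x: np.ndarray,
    y: np.ndarray,
    heading: np.ndarray,
    speed: np.ndarray,
    rng: np.random.Generator,
    width: float,
    height: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Turn uniformly within +/-45 degrees, then advance ``speed`` units.

    Speed-0 agents still turn but do not translate.  Positions wrap on the
    torus.
    """
    n = len(np.atleast_1d(x))
    turn = rng.uniform(-45.0, 45.0, n)
    heading = (np.atleast_1d(heading) + turn) % 360.0
    rad = np.deg2rad(heading)
    x = (np.atleast_1d(x) + speed * np.cos(rad)) % width
    y = (np.atleast_1d(y) + speed * np.sin(rad)) % height
    return x, y, heading


def tick_cost(
    trait: AgentTrait,
    changed: np.ndarray,
    cfg: WorldConfig,
    s_used: np.ndarray | None = None,
) -> np.ndarray:
    """Energy decrement per agent for one tick.

    ``c_e + (t + |S|) * c_b + (1 + S) * c_m`` on speed-change ticks and
    ``c_e + (t + |S|) * c_b + 1 * c_m`` otherwise, where ``t`` is the
    sensory investment ``d`` (sensory) or the switch probability ``K``
    (non-sensory).  For mixed strategies the realized S enters on change
    ticks and the mixture's mean |S| stands in on unchanged ticks.
    """
    changed = np.atleast_1d(np.asarray(changed, dtype=bool))
    n = len(changed)
    if s_used is None:
        s_used = np.full(n, float(trait.S) if not isinstance(trait.S, Mixture) else 0.0)
    s_used = np.atleast_1d(np.asarray(s_used, dtype=float))
    abs_s = np.where(changed, np.abs(s_used), trait.mean_abs_S)
    speed_factor = np.where(changed, 1.0 + s_used, 1.0)
    return cfg.c_e + (trait.cost_trait + abs_s) * cfg.c_b + speed_factor * cfg.c_m


class World:
    """Mutable simulation state plus the per-tick update rule."""

    def __init__(
        self,
        cfg: WorldConfig,
        prey_trait: AgentTrait,
        predator_trait: AgentTrait,
        rng: np.random.Generator,
        record_events: bool = False,
    ):
        if prey_trait.role != "prey" or predator_trait.role != "predator":
            raise ValueError("traits must be one prey and one predator")
        self.cfg = cfg
        self.prey_trait = prey_trait
        self.predator_trait = predator_trait
        self.rng = rng
        self.t = 0
        self._next_id = 0
        self.events: list[tuple] | None = [] if record_events else None
        w, h = cfg.world_width, cfg.world_height
        self.sheep = self._spawn(cfg.initial_sheep, prey_trait, cfg.sheep_gain_from_food)
        self.wolves = self._spawn(cfg.initial_wolves, predator_trait, cfg.wolf_gain_from_food)
        # grass: half the patches start green; brown ones part-way through regrowth
        self.grass_green = rng.random((w, h)) < 0.5
        self.regrow = np.where(
            self.grass_green, 0, rng.integers(1, cfg.grass_regrowth_time + 1, (w, h))
        )

    # -- helpers -----------------------------------------------------------

    def _new_ids(self, n: int) -> np.ndarray:
        ids = np.arange(self._next_id, self._next_id + n)
        self._next_id += n
        return ids

    def _birth_s(self, trait: AgentTrait, n: int) -> np.ndarray:
        if isinstance(trait.S, Mixture) and trait.sampling_rule == "per_birth":
            return trait.S.sample(self.rng, n)
        if isinstance(trait.S, Mixture):
            return np.zeros(n)
        return np.full(n, float(trait.S))

    def _spawn(self, n: int, trait: AgentTrait, gain: float) -> _Population:
        cfg = self.cfg
        pop = _Population(
            x=self.rng.uniform(0, cfg.world_width, n),
            y=self.rng.uniform(0, cfg.world_height, n),
            heading=self.rng.uniform(0, 360.0, n),
            energy=self.rng.uniform(0, 2 * gain, n),
            ids=self._new_ids(n),
            s_birth=self._birth_s(trait, n),
        )
        if self.events is not None:
            for i in range(n):
                self.events.append((self.t, "birth", int(pop.ids[i]), float(pop.energy[i])))
        return pop

    def _log(self, kind: str, ids: np.ndarray, amounts: Iterable[float]) -> None:
        if self.events is not None:
            for agent_id, amount in zip(ids, amounts):
                self.events.append((self.t, kind, int(agent_id), float(amount)))

    def _patches(self, pop: _Population) -> np.ndarray:
        ix = np.floor(pop.x).astype(int) % self.cfg.world_width
        iy = np.floor(pop.y).astype(int) % self.cfg.world_height
        return ix * self.cfg.world_height + iy

    def _reproduce(self, pop: _Population, trait: AgentTrait, percent: float) -> None:
        if pop.n == 0:
            return
        parents = self.rng.random(pop.n) < percent / 100.0
        k = int(parents.sum())
        if k == 0:
            return
        pop.energy[parents] /= 2.0
        self._log("reproduce_half", pop.ids[parents], pop.energy[parents])
        child = _Population(
            x=pop.x[parents].copy(),
            y=pop.y[parents].copy(),
            heading=self.rng.uniform(0, 360.0, k),
            energy=pop.energy[parents].copy(),
            ids=self._new_ids(k),
            s_birth=self._birth_s(trait, k),
        )
        self._log("birth", child.ids, child.energy)
        pop.append(child)

    def _cull(self, pop: _Population) -> None:
        dead = pop.energy <= 0.0
        if dead.any():
            self._log("death_starve", pop.ids[dead], pop.energy[dead])
            pop.keep(~dead)

    # -- one tick ----------------------------------------------------------

    def step(self) -> TickRecord:
        """Prey phase, predator phase, grass phase; returns the tick record.

        Offspring spawned within a phase do not act until the next tick.
        Within the predator feeding step wolves are processed in a fresh
        random order and each eats at most one uniformly chosen co-located
        sheep.
        """
        cfg = self.cfg
        rng = self.rng
        W, H = float(cfg.world_width), float(cfg.world_height)
        E = 0

        # ---- prey phase
        sheep, wolves = self.sheep, self.wolves
        n_before_move = sheep.n
        if n_before_move:
            detected = sense(
                sheep.x, sheep.y, wolves.x, wolves.y, self.prey_trait.D, W, H
            ) if self.prey_trait.algorithm == "sensory" else np.zeros(n_before_move, bool)
            speed, changed, s_used = choose_speed(
                self.prey_trait, detected, rng, sheep.s_birth
            )
            sheep.x, sheep.y, sheep.heading = move(
                sheep.x, sheep.y, sheep.heading, speed, rng, W, H
            )
            # graze: one uniformly chosen sheep per green patch eats it
            patches = self._patches(sheep)
            order = rng.permutation(sheep.n)
            _, first_idx = np.unique(patches[order], return_index=True)
            eaters = order[first_idx]
            flat_green = self.grass_green.reshape(-1)
            eaters = eaters[flat_green[patches[eaters]]]
            if len(eaters):
                sheep.energy[eaters] += cfg.sheep_gain_from_food
                self._log("graze", sheep.ids[eaters], np.full(len(eaters), cfg.sheep_gain_from_food))
                flat_green[patches[eaters]] = False
                self.regrow.reshape(-1)[patches[eaters]] = cfg.grass_regrowth_time
            cost = tick_cost(self.prey_trait, changed, cfg, s_used)
            sheep.energy -= cost
            self._log("cost", sheep.ids, -cost)
            self._reproduce(sheep, self.prey_trait, cfg.sheep_reproduce)
            self._cull(sheep)

        # ---- predator phase
        if wolves.n:
            detected = sense(
                wolves.x, wolves.y, sheep.x, sheep.y, self.predator_trait.D, W, H
            ) if self.predator_trait.algorithm == "sensory" else np.zeros(wolves.n, bool)
            speed, changed, s_used = choose_speed(
                self.predator_trait, detected, rng, wolves.s_birth
            )
            wolves.x, wolves.y, wolves.heading = move(
                wolves.x, wolves.y, wolves.heading, speed, rng, W, H
            )
            # feeding: sequential in random order over a patch -> sheep map
            if sheep.n:
                sheep_patches = self._patches(sheep)
                by_patch: dict[int, list[int]] = {}
                for idx, pc in enumerate(sheep_patches):
                    by_patch.setdefault(int(pc), []).append(idx)
                wolf_patches = self._patches(wolves)
                eaten: list[int] = []
                for wi in rng.permutation(wolves.n):
                    pool = by_patch.get(int(wolf_patches[wi]))
                    if pool:
                        victim = pool.pop(int(rng.integers(len(pool))))
                        eaten.append(victim)
                        wolves.energy[wi] += cfg.wolf_gain_from_food
                        self._log("predation_gain", wolves.ids[wi : wi + 1], [cfg.wolf_gain_from_food])
                        E += 1
                if eaten:
                    mask = np.ones(sheep.n, bool)
                    mask[eaten] = False
                    self._log("death_eaten", sheep.ids[~mask], sheep.energy[~mask])
                    sheep.keep(mask)
            cost = tick_cost(self.predator_trait, changed, cfg, s_used)
            wolves.energy -= cost
            self._log("cost", wolves.ids, -cost)
            self._reproduce(wolves, self.predator_trait, cfg.r)
            self._cull(wolves)

        # ---- grass phase
        brown = ~self.grass_green
        self.regrow[brown] -= 1
        regrown = brown & (self.regrow <= 0)
        self.grass_green[regrown] = True
        self.regrow[regrown] = 0

        rec = TickRecord(t=self.t, E=E, N_w=self.wolves.n, N_s=self.sheep.n)
        self.t += 1
        return rec


@dataclass
class RunResult:
    """Full tick series of one run plus the measurement-window slice."""

    ticks: pd.DataFrame
    cfg: WorldConfig
    prey_trait: AgentTrait
    predator_trait: AgentTrait
    seed: object
    events: list | None = None
    final_sheep: pd.DataFrame | None = None
    final_wolves: pd.DataFrame | None = None

    @property
    def window(self) -> pd.DataFrame:
        lo, hi = self.cfg.window
        return self.ticks[(self.ticks["t"] >= lo) & (self.ticks["t"] < hi)]


def run(
    cfg: WorldConfig,
    prey_trait: AgentTrait,
    predator_trait: AgentTrait,
    seed,
    record_events: bool = False,
) -> RunResult:
    """Simulate ``cfg.horizon`` ticks; fully reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    world = World(cfg, prey_trait, predator_trait, rng, record_events=record_events)
    records = [world.step() for _ in range(cfg.horizon)]
    ticks = pd.DataFrame(
        {
            "t": [r.t for r in records],
            "E": [r.E for r in records],
            "N_w": [r.N_w for r in records],
            "N_s": [r.N_s for r in records],
        }
    )
    def _roster(pop):
        return pd.DataFrame({"id": pop.ids, "energy": pop.energy})

    return RunResult(
        ticks=ticks,
        cfg=cfg,
        prey_trait=prey_trait,
        predator_trait=predator_trait,
        seed=seed,
        events=world.events,
        final_sheep=_roster(world.sheep),
        final_wolves=_roster(world.wolves),
    )
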