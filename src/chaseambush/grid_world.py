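"""Exact encounter-probability enumeration for a single predator and prey on a lattice.

A predator ("wolf") is anchored at the centre of a small lattice and a prey
("sheep") is placed at every other admissible cell.  Each agent senses the
opponent within a Chebyshev detection radius ``D`` and, when it detects,
changes its speed from the default 1 to ``1 + S`` with speed delta
``S in {-1, 0, 1}`` (ambush/freeze, no change, chase/escape).  A single
synchronous step is then taken and an encounter is scored iff the two agents
occupy the same cell at the end of the step.  Probabilities are exact
rationals: (number of encounters) / (total number of cases), uniform over all
initial placements and both agents' possible moves.

Movement convention
-------------------
An agent moving at speed ``s`` lands on a uniformly chosen cell of the
Chebyshev ring of radius ``s`` around its start (its set of possible next
positions): 1 case for speed 0 (the heading is irrelevant for a stationary
agent), the 8 Moore neighbours for speed 1, and the 16 ring-2 cells for
speed 2.  The lattice bounds constrain only the initial placement; the step
itself is taken on an unbounded plane, so only relative displacement matters
and the predator/prey role-swap symmetry is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product

__all__ = [
    "SPEED_DELTAS",
    "GridSpec",
    "GridBehavior",
    "EncounterTally",
    "ring_moves",
    "chebyshev",
    "initial_configurations",
    "step_outcome",
    "encounter_probability",
    "grid_bimatrix",
    "landscape",
]

#: Speed deltas available to each grid-world agent, ascending.
SPEED_DELTAS: tuple[int, ...] = (-1, 0, 1)

#: Detection radii considered in the grid world.
DETECTION_RADII: tuple[int, ...] = (0, 1, 2)

VARIANTS = ("single_step_exclusive", "adjacent_inclusive")


class InvalidSpecError(ValueError):
    """Raised when a grid specification cannot host the requested radii."""


def chebyshev(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Chebyshev (chessboard) distance between two lattice cells."""
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


def ring_moves(radius: int) -> tuple[tuple[int, int], ...]:
    """All displacements landing on the Chebyshev ring of ``radius``.

    ``radius == 0`` yields the single stay-put displacement; a stationary
    agent contributes exactly one case to the enumeration rather than eight.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if radius == 0:
        return ((0, 0),)
    r = radius
    return tuple(
        (dx, dy)
        for dx in range(-r, r + 1)
        for dy in range(-r, r + 1)
        if max(abs(dx), abs(dy)) == r
    )


@dataclass(frozen=True)
class GridSpec:
    """Geometry and enumeration variant of the single-pair grid world.

    ``single_step_exclusive`` drops initial placements where the agents are
    already adjacent whenever either detection radius is 2 (detection at the
    outer edge of the range); ``adjacent_inclusive`` keeps them, which is
    equivalent to allowing a two-step interaction.
    """

    lattice_extent: int = 5
    predator_anchor: tuple[int, int] = (2, 2)
    variant: str = "single_step_exclusive"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise InvalidSpecError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        x, y = self.predator_anchor
        n = self.lattice_extent
        if not (0 <= x < n and 0 <= y < n):
            raise InvalidSpecError(f"predator anchor {self.predator_anchor} outside {n}x{n} lattice")

    def validate_radius(self, D: int) -> None:
        if D < 0 or 2 * D + 1 > self.lattice_extent:
            raise InvalidSpecError(
                f"detection radius {D} cannot be hosted by a {self.lattice_extent}x{self.lattice_extent} lattice"
            )


@dataclass(frozen=True)
class GridBehavior:
    """A (detection radius, speed delta) pair for one grid-world agent."""

    D: int
    S: int

    def __post_init__(self) -> None:
        if self.D not in DETECTION_RADII:
            raise ValueError(f"detection radius must be one of {DETECTION_RADII}, got {self.D}")
        if self.S not in SPEED_DELTAS:
            raise ValueError(f"speed delta must be one of {SPEED_DELTAS}, got {self.S}")

    @property
    def speed_when_detecting(self) -> int:
        return 1 + self.S


@dataclass(frozen=True)
class EncounterTally:
    """Exact encounter count over an exhaustive case enumeration."""

    encounters: int
    total_cases: int

    def __post_init__(self) -> None:
        if self.total_cases <= 0:
            raise ValueError("total_cases must be positive")
        if not 0 <= self.encounters <= self.total_cases:
            raise ValueError("encounters must lie in [0, total_cases]")

    @property
    def p(self) -> Fraction:
        """Encounter probability as an exact rational."""
        return Fraction(self.encounters, self.total_cases)


def initial_configurations(
    spec: GridSpec, D_w: int, D_s: int
) -> list[tuple[int, int]]:
    """Admissible prey start cells given the variant and detection radii.

    Every lattice cell except the predator anchor; under the single-step
    variant with ``max(D_w, D_s) == 2`` the cells adjacent to the anchor
    (Chebyshev distance 1) are additionally removed, because at radius 2 the
    agents would already have detected each other before reaching adjacency.
    """
    spec.validate_radius(D_w)
    spec.validate_radius(D_s)
    n = spec.lattice_extent
    anchor = spec.predator_anchor
    cells = [(x, y) for x in range(n) for y in range(n) if (x, y) != anchor]
    if spec.variant == "single_step_exclusive" and max(D_w, D_s) == 2:
        cells = [c for c in cells if chebyshev(c, anchor) >= 2]
    return cells


def step_outcome(
    predator_cell: tuple[int, int],
    prey_cell: tuple[int, int],
    predator_move: tuple[int, int],
    prey_move: tuple[int, int],
) -> tuple[tuple[tuple[int, int], tuple[int, int]], bool]:
    """Apply one synchronous step and report the encounter flag.

    ``*_move`` are displacement vectors drawn from :func:`ring_moves` of the
    agent's speed.  The encounter is scored at the end of the step only; a
    fast agent passing over the opponent's cell mid-step does not count.
    """
    pred_final = (predator_cell[0] + predator_move[0], predator_cell[1] + predator_move[1])
    prey_final = (prey_cell[0] + prey_move[0], prey_cell[1] + prey_move[1])
    return (pred_final, prey_final), pred_final == prey_final


def encounter_probability(
    D_w: int, D_s: int, S_w: int, S_s: int, spec: GridSpec | None = None
) -> EncounterTally:
    """Exact single-step encounter probability for one trait combination.

    Enumerates every admissible prey start cell, evaluates detection once on
    the initial positions (Chebyshev distance <= D_i), sets each agent's
    speed to ``1 + S_i`` if it detects and 1 otherwise, and counts encounters
    over the cross product of both agents' possible moves with uniform
    weighting.
    """
    if spec is None:
        spec = GridSpec()
    if S_w not in SPEED_DELTAS or S_s not in SPEED_DELTAS:
        raise ValueError(f"speed deltas must be in {SPEED_DELTAS}")
    anchor = spec.predator_anchor
    encounters = 0
    total = 0
    for prey in initial_configurations(spec, D_w, D_s):
        d = chebyshev(prey, anchor)
        pred_speed = 1 + S_w if d <= D_w else 1
        prey_speed = 1 + S_s if d <= D_s else 1
        for pred_move, prey_move in product(ring_moves(pred_speed), ring_moves(prey_speed)):
            total += 1
            _, hit = step_outcome(anchor, prey, pred_move, prey_move)
            if hit:
                encounters += 1
    return EncounterTally(encounters, total)


def grid_bimatrix(D_w: int, D_s: int, spec: GridSpec | None = None):
    """3x3 constant-sum payoff bimatrix for one detection-radius combination.

    Rows are prey speed deltas ascending, columns predator speed deltas
    ascending; the prey entry is ``1 - p`` and the predator entry ``p``, kept
    as exact rationals so that each cell sums to 1 exactly.
    """
    from .nash import PayoffBimatrix

    if spec is None:
        spec = GridSpec()
    prey = [
        [1 - encounter_probability(D_w, D_s, S_w, S_s, spec).p for S_w in SPEED_DELTAS]
        for S_s in SPEED_DELTAS
    ]
    pred = [[1 - v for v in row] for row in prey]
    return PayoffBimatrix(
        row_labels=list(SPEED_DELTAS),
        col_labels=list(SPEED_DELTAS),
        prey_payoffs=prey,
        predator_payoffs=pred,
        provenance={
            "source": "grid_world",
            "D_w": D_w,
            "D_s": D_s,
            "variant": spec.variant,
        },
    )


def landscape(spec: GridSpec | None = None):
    """Long-format table of all 81 (D_w, D_s, S_w, S_s) encounter tallies.

    Returns a pandas DataFrame with one row per trait combination; ``p`` is
    carried both as an exact "num/den" string and as a float.
    """
    import pandas as pd

    if spec is None:
        spec = GridSpec()
    rows = []
    for D_s, D_w, S_s, S_w in product(
        DETECTION_RADII, DETECTION_RADII, SPEED_DELTAS, SPEED_DELTAS
    ):
        t = encounter_probability(D_w, D_s, S_w, S_s, spec)
        rows.append(
            {
                "variant": spec.variant,
                "D_s": D_s,
                "D_w": D_w,
                "S_s": S_s,
                "S_w": S_w,
                "encounters": t.encounters,
                "total_cases": t.total_cases,
                "p_exact": f"{t.p.numerator}/{t.p.denominator}",
                "p": float(t.p),
            }
        )
    return pd.DataFrame(rows)
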