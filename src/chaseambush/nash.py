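"""Bimatrix games and Nash equilibrium computation by support enumeration.

The games here are small (3x3 for the grid world, 11x11 for the
individual-based model), so exhaustive support enumeration is both feasible
and complete for nondegenerate games: for every candidate pair of supports
the indifference conditions form a linear system whose solution, if it is a
valid probability vector and survives the best-response certificate, is an
equilibrium.  Degenerate games (ties, constant rows -- e.g. an extinct
predator whose payoff table is identically zero) are handled by also testing
unequal-size support pairs and reporting the extreme equilibria found.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "PayoffBimatrix",
    "Equilibrium",
    "find_equilibria",
    "verify_equilibrium",
    "classify_equilibrium",
]


class InvalidGameError(ValueError):
    pass


@dataclass
class PayoffBimatrix:
    """Labelled two-player payoff tables (prey chooses rows, predator columns).

    Entries may be exact :class:`fractions.Fraction` (grid world) or floats
    (simulation-derived); computations convert to float, while the exact
    entries are preserved for serialization.
    """

    row_labels: list
    col_labels: list
    prey_payoffs: Sequence[Sequence]
    predator_payoffs: Sequence[Sequence]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        A = np.asarray(self.prey_payoffs, dtype=float)
        B = np.asarray(self.predator_payoffs, dtype=float)
        if A.shape != B.shape or A.ndim != 2:
            raise InvalidGameError("payoff tables must be two same-shape 2-D tables")
        if A.shape != (len(self.row_labels), len(self.col_labels)):
            raise InvalidGameError("payoff table shape does not match labels")
        if not (np.isfinite(A).all() and np.isfinite(B).all()):
            raise InvalidGameError("payoff entries must be finite")
        if list(self.row_labels) != sorted(self.row_labels) or list(
            self.col_labels
        ) != sorted(self.col_labels):
            raise InvalidGameError("labels must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_labels), len(self.col_labels))

    def as_float(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.asarray(self.prey_payoffs, dtype=float),
            np.asarray(self.predator_payoffs, dtype=float),
        )

    def to_long_frame(self):
        """Long-format DataFrame (one row per cell) for CSV export."""
        import pandas as pd

        rows = []
        for i, rl in enumerate(self.row_labels):
            for j, cl in enumerate(self.col_labels):
                rows.append(
                    {
                        "S_s": rl,
                        "S_w": cl,
                        "prey_payoff": float(self.prey_payoffs[i][j]),
                        "predator_payoff": float(self.predator_payoffs[i][j]),
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_long_frame(cls, df, provenance: dict | None = None) -> "PayoffBimatrix":
        rows = sorted(df["S_s"].unique())
        cols = sorted(df["S_w"].unique())
        A = np.full((len(rows), len(cols)), np.nan)
        B = np.full((len(rows), len(cols)), np.nan)
        ri = {v: i for i, v in enumerate(rows)}
        ci = {v: j for j, v in enumerate(cols)}
        for rec in df.itertuples():
            A[ri[rec.S_s], ci[rec.S_w]] = rec.prey_payoff
            B[ri[rec.S_s], ci[rec.S_w]] = rec.predator_payoff
        if np.isnan(A).any() or np.isnan(B).any():
            raise InvalidGameError("long-format table does not cover the full grid")
        return cls(rows, cols, A, B, provenance or {})


@dataclass
class Equilibrium:
    """A Nash equilibrium: one mixture per player plus diagnostics."""

    prey_mixture: np.ndarray
    predator_mixture: np.ndarray
    prey_value: float
    predator_value: float
    support_rows: tuple[int, ...]
    support_cols: tuple[int, ...]
    classification: str = "unclassified"

    def to_dict(self, game: PayoffBimatrix | None = None) -> dict:
        d = {
            "prey_mixture": [float(v) for v in self.prey_mixture],
            "predator_mixture": [float(v) for v in self.predator_mixture],
            "prey_value": self.prey_value,
            "predator_value": self.predator_value,
            "support_rows": list(self.support_rows),
            "support_cols": list(self.support_cols),
            "classification": self.classification,
        }
        if game is not None:
            d["row_labels"] = list(game.row_labels)
            d["col_labels"] = list(game.col_labels)
        return d


_SNAP = 1e-12  # mixture entries below this are treated as exact zeros


def _solve_indifference(P: np.ndarray, active: Sequence[int], support: Sequence[int], tol: float):
    """Mixture over ``support`` making every strategy in ``active`` indifferent.

    ``P[i, j]`` is the payoff to the *row* player of pure row ``i`` against
    pure column ``j``; the returned vector mixes the *columns* in ``support``.
    Returns None when the linear system has no acceptable solution.
    """
    k = len(support)
    m = len(active)
    # difference equations between consecutive active strategies + normalization
    rows = []
    rhs = []
    sub = P[np.ix_(active, support)]
    for a in range(m - 1):
        rows.append(sub[a] - sub[a + 1])
        rhs.append(0.0)
    rows.append(np.ones(k))
    rhs.append(1.0)
    M = np.array(rows)
    b = np.array(rhs)
    if M.shape[0] == M.shape[1]:
        try:
            y = np.linalg.solve(M, b)
        except np.linalg.LinAlgError:
            y, *_ = np.linalg.lstsq(M, b, rcond=None)
    else:
        y, *_ = np.linalg.lstsq(M, b, rcond=None)
    if not np.all(np.isfinite(y)):
        return None
    if np.max(np.abs(M @ y - b)) > max(tol, 1e-9):
        return None
    if np.any(y < -max(tol, 1e-9)):
        return None
    y = np.clip(y, 0.0, None)
    y[y < _SNAP] = 0.0
    s = y.sum()
    if s <= 0:
        return None
    return y / s


def verify_equilibrium(
    game: PayoffBimatrix, eq: Equilibrium, tol: float = 1e-9
) -> tuple[bool, float]:
    """Best-response certificate: no pure deviation gains more than ``tol``.

    Returns (passed, worst deviation), where the worst deviation is the
    largest payoff improvement any pure strategy achieves over the player's
    equilibrium value against the opponent's mixture.
    """
    A, B = game.as_float()
    x = np.asarray(eq.prey_mixture, dtype=float)
    y = np.asarray(eq.predator_mixture, dtype=float)
    if x.shape != (A.shape[0],) or y.shape != (A.shape[1],):
        raise InvalidGameError("mixture shapes do not match the game")
    prey_payoffs = A @ y
    pred_payoffs = x @ B
    v_prey = float(x @ prey_payoffs)
    v_pred = float(pred_payoffs @ y)
    worst = max(float(prey_payoffs.max() - v_prey), float(pred_payoffs.max() - v_pred))
    return worst <= tol, worst


def classify_equilibrium(
    eq: Equilibrium, game: PayoffBimatrix, payoff_spread_tol: float = 1e-9
) -> str:
    """Classify supports: pure / mixed_both / mixed_partial / indeterminate.

    ``indeterminate`` flags a player whose payoff does not depend on its own
    strategy at all (each column of its table is constant within
    ``payoff_spread_tol``) -- the "any value" cases such as an extinct
    predator's identically-zero table, where the solver's choice of support
    carries no information.  Mere equilibrium indifference (payoffs flat
    given the opponent's *mixture*, as at any full-support equilibrium) does
    not qualify.
    """
    A, B = game.as_float()
    prey_flat = float(np.max(A.max(axis=0) - A.min(axis=0))) <= payoff_spread_tol
    pred_flat = float(np.max(B.max(axis=1) - B.min(axis=1))) <= payoff_spread_tol
    if prey_flat or pred_flat:
        return "indeterminate"
    nr = len(eq.support_rows)
    nc = len(eq.support_cols)
    if nr == 1 and nc == 1:
        return "pure"
    if nr >= 2 and nc >= 2:
        return "mixed_both"
    return "mixed_partial"


def _support_pairs(n_rows: int, n_cols: int, include_unequal: bool, max_support: int | None):
    kr = range(1, n_rows + 1) if max_support is None else range(1, min(n_rows, max_support) + 1)
    kc = range(1, n_cols + 1) if max_support is None else range(1, min(n_cols, max_support) + 1)
    for a in kr:
        for b in kc:
            if not include_unequal and a != b:
                continue
            for I in itertools.combinations(range(n_rows), a):
                for J in itertools.combinations(range(n_cols), b):
                    yield I, J


def find_equilibria(
    game: PayoffBimatrix,
    tol: float = 1e-9,
    include_unequal: bool | None = None,
    max_support: int | None = None,
) -> list[Equilibrium]:
    """All extreme Nash equilibria found by support enumeration.

    For each support pair the opponent mixtures are solved from the
    indifference conditions and kept only if they pass the best-response
    certificate at ``tol``.  ``include_unequal`` controls whether unequal-size
    support pairs are tested (needed for degenerate games); by default it is
    on for games with at most 6 strategies per side and off for larger ones.
    ``max_support`` caps the support size for large games; ``None`` means the
    full range for small games and 4 per side for games larger than 6x6.

    Duplicates within ``tol`` are merged and the result is ordered
    lexicographically by (support_rows, support_cols, mixtures).
    """
    A, B = game.as_float()
    n_rows, n_cols = A.shape
    big = max(n_rows, n_cols) > 6
    if include_unequal is None:
        include_unequal = not big
    if max_support is None and big:
        max_support = 4

    found: list[Equilibrium] = []
    for I, J in _support_pairs(n_rows, n_cols, include_unequal, max_support):
        # predator mixture y over J making prey rows in I indifferent
        y_sub = _solve_indifference(A, I, J, tol)
        if y_sub is None:
            continue
        # prey mixture x over I making predator columns in J indifferent
        x_sub = _solve_indifference(B.T, J, I, tol)
        if x_sub is None:
            continue
        x = np.zeros(n_rows)
        y = np.zeros(n_cols)
        x[list(I)] = x_sub
        y[list(J)] = y_sub
        eq = Equilibrium(
            prey_mixture=x,
            predator_mixture=y,
            prey_value=float(x @ A @ y),
            predator_value=float(x @ B @ y),
            support_rows=tuple(i for i in range(n_rows) if x[i] > 0),
            support_cols=tuple(j for j in range(n_cols) if y[j] > 0),
        )
        ok, _ = verify_equilibrium(game, eq, max(tol, 1e-9))
        if not ok:
            continue
        eq.classification = classify_equilibrium(eq, game, payoff_spread_tol=max(tol, 1e-9))
        found.append(eq)

    # merge duplicates (same mixtures within tol), keep deterministic order
    merged: list[Equilibrium] = []
    for eq in found:
        dup = False
        for other in merged:
            if (
                np.max(np.abs(eq.prey_mixture - other.prey_mixture)) <= max(tol, 1e-7)
                and np.max(np.abs(eq.predator_mixture - other.predator_mixture)) <= max(tol, 1e-7)
            ):
                dup = True
                break
        if not dup:
            merged.append(eq)
    merged.sort(
        key=lambda e: (
            e.support_rows,
            e.support_cols,
            tuple(np.round(e.prey_mixture, 12)),
            tuple(np.round(e.predator_mixture, 12)),
        )
    )
    return merged
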