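"""From tick records to payoffs, window summaries and payoff bimatrices.

Per tick, the encounter probabilities are ``p_w = E / N_w`` for the predator
and ``p_s = E / (E + N_s)`` for the prey (``N_s`` excludes the sheep eaten
that tick, so ``E + N_s`` restores the pre-interaction prey count).  The
payoffs are ``P_w = p_w`` (probability of encountering prey) and
``P_s = 1 - p_s`` (probability of evading predation), with
``P_diff = P_s - P_w``.  Ratios are computed per tick and then averaged over
the measurement window -- not the other way around.  An empty predator
roster contributes ``p_w = 0`` (the predator-extinction convention that puts
mass at ``P_w = 0``); an empty pre-interaction prey roster contributes
``p_s = 0`` and flags prey extinction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abm import AgentTrait, Mixture, WorldConfig, run
from .nash import PayoffBimatrix

__all__ = [
    "MeasurementSummary",
    "tick_payoffs",
    "summarize",
    "sweep_payoff_matrix",
    "game_sum_class",
]

_SUM_TOL = 1e-9


class InvalidRecordError(ValueError):
    pass


@dataclass
class MeasurementSummary:
    """Window-averaged measurements of one run."""

    mean_E: float
    mean_N_w: float
    mean_N_s: float
    mean_P_w: float
    mean_P_s: float
    mean_P_diff: float
    predator_extinct: bool
    prey_extinct: bool
    n_ticks_averaged: int
    condition: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dict(self.condition)
        d.update(
            mean_E=self.mean_E,
            mean_N_w=self.mean_N_w,
            mean_N_s=self.mean_N_s,
            mean_P_w=self.mean_P_w,
            mean_P_s=self.mean_P_s,
            mean_P_diff=self.mean_P_diff,
            predator_extinct=self.predator_extinct,
            prey_extinct=self.prey_extinct,
            n_ticks_averaged=self.n_ticks_averaged,
        )
        return d


def tick_payoffs(E: int, N_w: int, N_s: int) -> tuple[float, float, float, float, float]:
    """(p_w, p_s, P_w, P_s, P_diff) for one tick record."""
    if min(E, N_w, N_s) < 0:
        raise InvalidRecordError("tick counts must be non-negative")
    p_w = E / N_w if N_w > 0 else 0.0
    p_s = E / (E + N_s) if (E + N_s) > 0 else 0.0
    P_w = p_w
    P_s = 1.0 - p_s
    return p_w, p_s, P_w, P_s, P_s - P_w


def summarize(
    ticks: pd.DataFrame,
    window: tuple[int, int] | None = None,
    condition: dict | None = None,
) -> MeasurementSummary:
    """Window means of E, N_i and the per-tick payoffs.

    The payoff ratio is evaluated at every tick and the resulting series is
    averaged; extinction flags are set when the respective roster is empty at
    any tick of the window.
    """
    df = ticks
    if window is not None:
        lo, hi = window
        df = ticks[(ticks["t"] >= lo) & (ticks["t"] < hi)]
    if len(df) == 0:
        raise ValueError("measurement window contains no ticks")
    E = df["E"].to_numpy(dtype=float)
    N_w = df["N_w"].to_numpy(dtype=float)
    N_s = df["N_s"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_w = np.where(N_w > 0, E / N_w, 0.0)
        pre_prey = E + N_s
        p_s = np.where(pre_prey > 0, E / np.where(pre_prey > 0, pre_prey, 1.0), 0.0)
    P_w = p_w
    P_s = 1.0 - p_s
    return MeasurementSummary(
        mean_E=float(E.mean()),
        mean_N_w=float(N_w.mean()),
        mean_N_s=float(N_s.mean()),
        mean_P_w=float(P_w.mean()),
        mean_P_s=float(P_s.mean()),
        mean_P_diff=float((P_s - P_w).mean()),
        predator_extinct=bool((N_w == 0).any()),
        prey_extinct=bool((pre_prey == 0).any()),
        n_ticks_averaged=len(df),
        condition=dict(condition or {}),
    )


def game_sum_class(summary: MeasurementSummary, tol: float = _SUM_TOL) -> str:
    """constant_sum / positive_sum / negative_sum from the payoff sum."""
    s = summary.mean_P_s + summary.mean_P_w
    if s > 1.0 + tol:
        return "positive_sum"
    if abs(s - 1.0) <= tol:
        return "constant_sum"
    return "negative_sum"


def _condition_seed(master_seed: int, *indices: int) -> np.random.SeedSequence:
    """Substream derived from (condition, repeat) so sweep order is irrelevant."""
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(i) for i in indices))


def sweep_payoff_matrix(
    cfg: WorldConfig,
    prey_template: AgentTrait,
    predator_template: AgentTrait,
    S_grid: tuple[float, ...],
    repeats: int,
    master_seed: int,
    condition: dict | None = None,
    condition_index: int = 0,
) -> tuple[PayoffBimatrix, list[PayoffBimatrix], pd.DataFrame]:
    """Run the IBM for every (S_s, S_w) cell and assemble payoff bimatrices.

    Each of the ``len(S_grid)**2 * repeats`` runs uses a seed substream
    derived from ``(master_seed, condition_index, cell, repeat)`` so that a
    partial or re-ordered sweep reproduces the full one.  Cell payoffs are
    the window means of ``P_s`` (prey table) and ``P_w`` (predator table).
    Returns the across-repeat mean bimatrix, the per-repeat bimatrices and
    the long-format summary table.
    """
    from dataclasses import replace

    S_grid = tuple(float(s) for s in S_grid)
    n = len(S_grid)
    prey_tab = np.zeros((repeats, n, n))
    pred_tab = np.zeros((repeats, n, n))
    rows = []
    for ci, S_s in enumerate(S_grid):
        for cj, S_w in enumerate(S_grid):
            cell = ci * n + cj
            prey_trait = replace(prey_template, S=S_s)
            predator_trait = replace(predator_template, S=S_w)
            for rep in range(repeats):
                seed = _condition_seed(master_seed, condition_index, cell, rep)
                res = run(cfg, prey_trait, predator_trait, seed)
                summ = summarize(res.ticks, cfg.window)
                prey_tab[rep, ci, cj] = summ.mean_P_s
                pred_tab[rep, ci, cj] = summ.mean_P_w
                rec = dict(condition or {})
                rec.update(repeat=rep, S_s=S_s, S_w=S_w, **{
                    k: v for k, v in summ.to_dict().items() if k.startswith(("mean_", "predator_", "prey_", "n_ticks"))
                })
                rows.append(rec)
    prov = dict(condition or {})

    def _mat(prey_block, pred_block, extra):
        p = dict(prov)
        p.update(extra)
        return PayoffBimatrix(
            row_labels=list(S_grid),
            col_labels=list(S_grid),
            prey_payoffs=prey_block,
            predator_payoffs=pred_block,
            provenance=p,
        )

    mean_matrix = _mat(prey_tab.mean(axis=0), pred_tab.mean(axis=0), {"repeat": "mean"})
    per_repeat = [
        _mat(prey_tab[r], pred_tab[r], {"repeat": r}) for r in range(repeats)
    ]
    return mean_matrix, per_repeat, pd.DataFrame(rows)
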