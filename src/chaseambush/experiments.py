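"""Equilibrium-assignment runs, behavioral-switching reports and algorithm comparison.

Once a Nash equilibrium is computed for a condition, the corresponding
mixtures are handed back to the simulator: each agent redraws its speed
delta from its equilibrium mixture on every tick where its speed change
fires (behavioral switching), and realized payoffs are measured over the
usual window.  The reports group conditions by switching class and
encounter level, and the final comparison contrasts the two motor
algorithms' distributions of E, N_i and payoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .abm import AgentTrait, Mixture, WorldConfig, run
from .nash import Equilibrium, PayoffBimatrix
from .payoffs import MeasurementSummary, _condition_seed, summarize

__all__ = [
    "EquilibriumAssignment",
    "assignment_from_equilibrium",
    "realize_mixed_behavior",
    "measure_equilibrium",
    "select_equilibrium",
    "switching_report",
    "algorithm_comparison",
]


def select_equilibrium(eqs: list, game: PayoffBimatrix):
    """Deterministic choice among multiple equilibria.

    A unique equilibrium is returned as-is.  Otherwise prefer, in order:
    one whose supports sit on the extreme speed deltas for both players
    (the chase/ambush x escape/freeze corners), then one with both-side
    mixing, then the first in the solver's deterministic order.  The
    multiplicity itself is preserved by the caller; this rule only picks the
    representative handed to downstream consumers.
    """
    if not eqs:
        raise ValueError("no equilibria to select from")
    if len(eqs) == 1:
        return eqs[0]
    corners_r = {0, len(game.row_labels) - 1}
    corners_c = {0, len(game.col_labels) - 1}
    for eq in eqs:
        if (
            len(eq.support_rows) == 2
            and len(eq.support_cols) == 2
            and set(eq.support_rows) <= corners_r
            and set(eq.support_cols) <= corners_c
        ):
            return eq
    for eq in eqs:
        if eq.classification == "mixed_both":
            return eq
    return eqs[0]


@dataclass(frozen=True)
class EquilibriumAssignment:
    """Per-role policies realizing a Nash equilibrium in the simulator."""

    prey_trait: AgentTrait
    predator_trait: AgentTrait
    condition: dict = field(default_factory=dict)
    classification: str = "unclassified"


def _policy_S(mixture: np.ndarray, labels: list, tol: float = 1e-9):
    """Collapse an equilibrium mixture to a scalar S or a Mixture policy."""
    probs = np.asarray(mixture, dtype=float)
    keep = probs > tol
    support = tuple(float(l) for l, k in zip(labels, keep) if k)
    p = probs[keep]
    p = p / p.sum()
    if len(support) == 1:
        return support[0]
    return Mixture(support=support, probs=tuple(float(v) for v in p))


def assignment_from_equilibrium(
    eq: Equilibrium,
    game: PayoffBimatrix,
    prey_template: AgentTrait,
    predator_template: AgentTrait,
    sampling_rule: str = "per_event",
) -> EquilibriumAssignment:
    """Turn a solved equilibrium into simulator policies.

    For an indeterminate side (payoffs flat across its strategies, e.g. an
    extinct predator) the mixture is kept as solved; any fixed S would do
    and the solver's choice is as good as any.
    """
    prey_S = _policy_S(eq.prey_mixture, game.row_labels)
    pred_S = _policy_S(eq.predator_mixture, game.col_labels)
    prey = replace(prey_template, S=prey_S, sampling_rule=sampling_rule)
    pred = replace(predator_template, S=pred_S, sampling_rule=sampling_rule)
    return EquilibriumAssignment(
        prey_trait=prey,
        predator_trait=pred,
        condition=dict(game.provenance),
        classification=eq.classification,
    )


def realize_mixed_behavior(
    policy, triggered: bool, rng: np.random.Generator
) -> float | None:
    """The S value an agent uses this tick, or None when untriggered.

    On each tick where the speed-change condition fires (detection for the
    sensory algorithm, a K-success for the non-sensory one) a mixed policy
    is sampled afresh; a scalar policy always returns itself.
    """
    if not triggered:
        return None
    if isinstance(policy, Mixture):
        return float(policy.sample(rng, 1)[0])
    return float(policy)


def measure_equilibrium(
    cfg: WorldConfig,
    assignment: EquilibriumAssignment,
    n_repeats: int = 10,
    master_seed: int = 0,
    condition_index: int = 0,
) -> list[MeasurementSummary]:
    """Independent runs under the assigned equilibrium policies."""
    out = []
    for rep in range(n_repeats):
        seed = _condition_seed(master_seed, condition_index, 10_000 + rep)
        res = run(cfg, assignment.prey_trait, assignment.predator_trait, seed)
        cond = dict(assignment.condition)
        cond.update(repeat=rep, classification=assignment.classification)
        out.append(summarize(res.ticks, cfg.window, condition=cond))
    return out


def _switch_class(classification: str) -> str:
    return {
        "mixed_both": "both",
        "mixed_partial": "partial",
    }.get(classification, "none")


def switching_report(
    summaries: list[MeasurementSummary], e_threshold: float = 4.0
) -> pd.DataFrame:
    """Per-run switching table: class, encounter group and payoffs.

    Groups are ``switching & mean_E > threshold``, ``switching & mean_E <=
    threshold`` and ``no switching``; a run exactly at the threshold falls
    in the ``<=`` group.  Percent-switching tables by (c_b, r) can be built
    by aggregating the returned frame.
    """
    rows = []
    for s in summaries:
        cls = _switch_class(str(s.condition.get("classification", "unclassified")))
        switching = cls in ("both", "partial")
        if switching and s.mean_E > e_threshold:
            group = "switching_high_E"
        elif switching:
            group = "switching_low_E"
        else:
            group = "no_switching"
        rec = s.to_dict()
        rec.update(switch_class=cls, group=group)
        rows.append(rec)
    return pd.DataFrame(rows)


def switching_percentages(report: pd.DataFrame, by=("c_b", "r")) -> pd.DataFrame:
    """Percent of conditions per (c_b, r) whose equilibrium mixes (by type)."""
    by = [b for b in by if b in report.columns]
    if not by:
        raise ValueError("report lacks grouping columns")
    def _pct(g):
        n = len(g)
        return pd.Series(
            {
                "pct_partial": 100.0 * (g["switch_class"] == "partial").sum() / n,
                "pct_both": 100.0 * (g["switch_class"] == "both").sum() / n,
                "n": n,
            }
        )
    return report.groupby(list(by)).apply(_pct, include_groups=False).reset_index()


def algorithm_comparison(
    sensory: list[MeasurementSummary],
    nonsensory: list[MeasurementSummary],
    bins: int = 10,
) -> dict:
    """Histogram and rank-test comparison of the two motor algorithms.

    Emits binned proportions of E, N_w, N_s, P_w and P_s per algorithm plus a
    Mann-Whitney rank comparison per quantity, reported descriptively (a
    common-language effect size alongside the statistic).
    """
    if len(sensory) == 0 or len(nonsensory) == 0:
        raise ValueError("both result sets must be non-empty")
    keys_s = {tuple(sorted((k, v) for k, v in s.condition.items() if k in ("c_b", "r"))) for s in sensory}
    keys_n = {tuple(sorted((k, v) for k, v in s.condition.items() if k in ("c_b", "r"))) for s in nonsensory}
    if keys_s != keys_n:
        raise ValueError("sensory and non-sensory sets cover different (c_b, r) grids")

    quantities = {
        "E": lambda s: s.mean_E,
        "N_w": lambda s: s.mean_N_w,
        "N_s": lambda s: s.mean_N_s,
        "P_w": lambda s: s.mean_P_w,
        "P_s": lambda s: s.mean_P_s,
    }
    out: dict = {"histograms": {}, "rank_tests": {}}
    for name, get in quantities.items():
        a = np.array([get(s) for s in sensory], dtype=float)
        b = np.array([get(s) for s in nonsensory], dtype=float)
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        if hi <= lo:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, bins + 1)
        ha, _ = np.histogram(a, bins=edges)
        hb, _ = np.histogram(b, bins=edges)
        out["histograms"][name] = {
            "edges": edges.tolist(),
            "sensory": (ha / ha.sum()).tolist(),
            "nonsensory": (hb / hb.sum()).tolist(),
        }
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            u, pval = len(a) * len(b) / 2.0, 1.0
        else:
            u, pval = stats.mannwhitneyu(a, b, alternative="two-sided")
        out["rank_tests"][name] = {
            "U": float(u),
            "p_value": float(pval),
            # P(sensory > nonsensory) + 0.5 P(tie): descriptive effect size
            "prob_superiority": float(u / (len(a) * len(b))),
        }
    return out
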