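"""Type 1 vs Type 2 comparisons and the time/effort substitution curve.

Type 1 agents adapt both the decision threshold ``theta`` and the effort
level ``phi`` to the prevailing cost of time; Type 2 agents adapt only
``theta``, with ``phi`` frozen at the value optimal under the baseline time
cost.  Because accuracy and decision time depend only on (theta, phi), both
agent types are scored against one shared performance table re-priced at
each time cost: the dominance invariant W(type1) >= W(type2) and the exact
baseline identity then hold by construction, without re-simulation noise.

The substitution curve tracks the Type 1 optimum across a log-spaced sweep
of the time cost: as time grows dearer, optimal agents spend less time
(DT* falls) and more effort per unit time (C_e* rises).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .effort import EffortCostParams
from .landscape import GridSpec, evaluate_landscape, optimal_cell, performance_table
from .sprt import EnvironmentParams

__all__ = [
    "ComparisonRecord",
    "SubstitutionPoint",
    "FitnessAdvantage",
    "default_c_time_sweep",
    "optimize_type1",
    "optimize_type2",
    "relative_fitness_advantage",
    "compare_across_time_costs",
    "substitution_curve",
]

#: |W2| below this is treated as a degenerate normalizer for the relative
#: fitness advantage.
W2_TOL = 1e-12


@dataclass(frozen=True)
class ComparisonRecord:
    """Optimal strategy and performance of one agent type at one time cost."""

    c_time: float
    agent_type: str  # "type1" | "type2"
    theta_opt: float
    phi_used: float
    p_correct: float
    mean_decision_time: float
    fitness: float


@dataclass(frozen=True)
class SubstitutionPoint:
    """Type 1 optimum summarized as expenditure on time vs effort."""

    c_time: float
    mean_dt_opt: float
    c_effort_opt: float
    total_effort_spend: float  # C_e* x DT*


class FitnessAdvantage(NamedTuple):
    relative: float
    absolute: float


def default_c_time_sweep(low: float = 0.01, high: float = 1.0, n: int = 20) -> np.ndarray:
    """Log-spaced time costs spanning two orders of magnitude (the default sweep)."""
    return np.geomspace(low, high, n)


def _record_from_cell(cell: pd.Series, c_time: float, agent_type: str) -> ComparisonRecord:
    return ComparisonRecord(
        c_time=float(c_time),
        agent_type=agent_type,
        theta_opt=float(cell["theta"]),
        phi_used=float(cell["phi"]),
        p_correct=float(cell["p_correct"]),
        mean_decision_time=float(cell["mean_dt"]),
        fitness=float(cell["fitness"]),
    )


def optimize_type1(
    env: EnvironmentParams,
    costs: EffortCostParams,
    grid: GridSpec,
    c_time: float,
    perf: pd.DataFrame | None = None,
) -> ComparisonRecord:
    """Full two-dimensional optimum over (theta, phi) at the given time cost."""
    scape = evaluate_landscape(env, costs, grid, c_time=c_time, perf=perf)
    return _record_from_cell(optimal_cell(scape), c_time, "type1")


def optimize_type2(
    env: EnvironmentParams,
    costs: EffortCostParams,
    grid: GridSpec,
    c_time: float,
    phi_fixed: float,
    perf: pd.DataFrame | None = None,
) -> ComparisonRecord:
    """One-dimensional optimum over theta at a frozen effort level.

    ``phi_fixed`` must be a grid value (it is the baseline Type 1 optimum,
    so it always is when the same grid is used throughout).
    """
    scape = evaluate_landscape(env, costs, grid, c_time=c_time, perf=perf)
    cells = scape.cells
    column = cells[np.isclose(cells["phi"], phi_fixed, rtol=0.0, atol=1e-12)]
    if column.empty:
        raise ValueError(f"phi_fixed={phi_fixed} is not a grid value")
    column = column[column["valid"]]
    if column.empty:
        raise ValueError(f"no valid cells at phi_fixed={phi_fixed}")
    w_max = column["fitness"].max()
    cell = column[column["fitness"] == w_max].sort_values("theta").iloc[0]
    return _record_from_cell(cell, c_time, "type2")


def relative_fitness_advantage(w1: float, w2: float) -> FitnessAdvantage:
    """Type 1's fitness edge over Type 2: ``(W1 - W2) / |W2|``.

    The absolute difference is always reported alongside; when ``|W2|`` is
    below tolerance the ratio is undefined (NaN) and a warning is issued.
    """
    absolute = w1 - w2
    if abs(w2) < W2_TOL:
        warnings.warn(
            "relative fitness advantage undefined: |W2| below tolerance; "
            "use the absolute difference",
            RuntimeWarning,
            stacklevel=2,
        )
        return FitnessAdvantage(math.nan, absolute)
    return FitnessAdvantage(absolute / abs(w2), absolute)


def compare_across_time_costs(
    env: EnvironmentParams,
    costs: EffortCostParams,
    grid: GridSpec,
    c_time_values: Sequence[float],
    baseline_c_time: float | None = None,
    perf: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Type 1 vs Type 2 across a sweep of time costs.

    The baseline (default: the environment's ``c_time``) must be in the
    sweep; Type 2's effort is frozen at the Type 1 optimum there.  Returns
    one row per (c_time, agent type) with the relative fitness advantage
    attached to both rows of each pair.
    """
    baseline = env.c_time if baseline_c_time is None else float(baseline_c_time)
    c_values = [float(c) for c in c_time_values]
    if not any(math.isclose(c, baseline, rel_tol=1e-12) for c in c_values):
        raise ValueError("c_time_values must include the baseline time cost")
    if perf is None:
        perf = performance_table(env, grid)
    base_rec = optimize_type1(env, costs, grid, baseline, perf=perf)
    phi_fixed = base_rec.phi_used

    rows = []
    for c in c_values:
        r1 = optimize_type1(env, costs, grid, c, perf=perf)
        r2 = optimize_type2(env, costs, grid, c, phi_fixed, perf=perf)
        adv = relative_fitness_advantage(r1.fitness, r2.fitness)
        for r in (r1, r2):
            rows.append(
                {
                    "c_time": r.c_time,
                    "type": r.agent_type,
                    "theta_opt": r.theta_opt,
                    "phi_used": r.phi_used,
                    "p_correct": r.p_correct,
                    "mean_dt": r.mean_decision_time,
                    "fitness": r.fitness,
                    "rel_advantage": adv.relative,
                }
            )
    return pd.DataFrame(rows)


def substitution_curve(
    env: EnvironmentParams,
    costs: EffortCostParams,
    grid: GridSpec,
    c_time_values: Sequence[float],
    perf: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Type 1 expenditure on time vs effort along a time-cost sweep.

    Returns one row per ``c_time`` with the optimal mean decision time,
    the per-sample effort cost at the optimum, and their product (the
    total effort spent per decision).
    """
    if perf is None:
        perf = performance_table(env, grid)
    rows = []
    for c in c_time_values:
        rec = optimize_type1(env, costs, grid, float(c), perf=perf)
        c_eff = costs.k * rec.phi_used / (1.0 - rec.phi_used)
        rows.append(
            {
                "c_time": float(c),
                "mean_dt_opt": rec.mean_decision_time,
                "c_effort_opt": c_eff,
                "total_effort_spend": c_eff * rec.mean_decision_time,
            }
        )
    return pd.DataFrame(rows)
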