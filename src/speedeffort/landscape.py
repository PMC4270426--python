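"""Fitness landscapes over the (threshold, effort) strategy grid.

For each grid cell the accuracy ``P_C`` and mean decision time ``DT`` are
obtained either from simulated ensembles (``mode="simulate"``, mirroring the
original stochastic procedure) or from the absorption oracle
(``mode="oracle"``, exact and fast; the default for optimization).  Fitness
is then

    W = B * P_C - (C_t + C_e(phi)) * DT,

the benefit of deciding correctly less the total time-and-effort cost of
the decision.  Because ``P_C`` and ``DT`` depend only on (theta, phi), the
performance table can be priced at many ``C_t`` values without re-running
any simulation; the experiments module relies on this.

Cells whose trials do not all terminate within the sample budget are marked
invalid and excluded from optimization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .effort import EffortCostParams
from .oracle import oracle_summary
from .sprt import EnvironmentParams, Policy, simulate_ensemble

__all__ = [
    "GridSpec",
    "Landscape",
    "Optimum",
    "fitness",
    "performance_table",
    "attach_fitness",
    "evaluate_landscape",
    "find_optimum",
    "optimal_cell",
    "is_single_peaked",
    "write_landscape",
]

logger = logging.getLogger(__name__)

#: Unabsorbed probability mass above which an oracle-mode cell is treated as
#: truncated (hence invalid), mirroring "any truncation invalidates a cell"
#: in simulate mode.
ORACLE_TRUNCATION_TOL = 1e-9

LANDSCAPE_COLUMNS = ["theta", "phi", "p_correct", "mean_dt", "c_effort", "fitness", "valid"]


def _default_theta() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0.55, 0.9901, 0.01), 10))


def _default_phi() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0.0, 0.9801, 0.02), 10))


@dataclass(frozen=True)
class GridSpec:
    """Discrete strategy grid and how to evaluate it.

    Defaults: theta from 0.55 to 0.99 in steps of 0.01, phi from 0 to 0.98
    in steps of 0.02 (phi = 1 is excluded because its effort cost
    diverges), oracle mode, 10^4 trials per cell in simulate mode, sample
    budget 10^4.
    """

    theta_values: tuple[float, ...] = field(default_factory=_default_theta)
    phi_values: tuple[float, ...] = field(default_factory=_default_phi)
    n_trials: int = 10_000
    t_max: int = 10_000
    seed: int = 0
    mode: str = "oracle"

    def __post_init__(self) -> None:
        th = np.asarray(self.theta_values, dtype=float)
        ph = np.asarray(self.phi_values, dtype=float)
        if th.size < 1 or ph.size < 1:
            raise ValueError("grid must have at least one theta and one phi value")
        if np.any(np.diff(th) <= 0) or np.any(np.diff(ph) <= 0):
            raise ValueError("theta_values and phi_values must be strictly increasing")
        if not (0.5 < th[0] and th[-1] < 1.0):
            raise ValueError("theta values must lie in (0.5, 1)")
        if not (0.0 <= ph[0] and ph[-1] < 1.0):
            raise ValueError("phi values must lie in [0, 1)")
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.t_max < 1:
            raise ValueError(f"t_max must be >= 1, got {self.t_max}")
        if self.mode not in ("oracle", "simulate"):
            raise ValueError(f"mode must be 'oracle' or 'simulate', got {self.mode!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.theta_values), len(self.phi_values))


@dataclass(frozen=True)
class Landscape:
    """A priced strategy grid: one row per (theta, phi) cell.

    ``cells`` has columns theta, phi, p_correct, mean_dt, c_effort,
    fitness, valid (ordered theta-major, matching the grid).
    """

    cells: pd.DataFrame
    env: EnvironmentParams
    costs: EffortCostParams
    grid: GridSpec
    c_time: float

    def fitness_matrix(self) -> np.ndarray:
        """Fitness as a (n_theta, n_phi) array; invalid cells are -inf."""
        w = self.cells["fitness"].to_numpy().reshape(self.grid.shape).copy()
        valid = self.cells["valid"].to_numpy().reshape(self.grid.shape)
        w[~valid] = -np.inf
        return w

    def valid_matrix(self) -> np.ndarray:
        return self.cells["valid"].to_numpy().reshape(self.grid.shape)


class Optimum(NamedTuple):
    theta_star: float
    phi_star: float


def fitness(
    p_correct: float | np.ndarray,
    mean_decision_time: float | np.ndarray,
    benefit: float,
    c_time: float,
    c_effort: float | np.ndarray,
):
    """Absolute fitness of a strategy: ``B * P_C - (C_t + C_e) * DT``."""
    return benefit * p_correct - (c_time + c_effort) * mean_decision_time


def performance_table(env: EnvironmentParams, grid: GridSpec) -> pd.DataFrame:
    """P_C, DT and truncation for every grid cell; cost-independent.

    In simulate mode each cell gets an independent RNG stream derived from
    ``(seed, theta_index, phi_index)``, so the table is reproducible and
    cells are statistically independent.
    """
    rows = []
    for i, theta in enumerate(grid.theta_values):
        for j, phi in enumerate(grid.phi_values):
            policy = Policy(theta=theta, phi=phi)
            if grid.mode == "oracle":
                s = oracle_summary(env, policy, grid.t_max)
                truncated = s.truncated_mass
                valid = truncated <= ORACLE_TRUNCATION_TOL
                p_c, dt = s.p_correct, s.mean_decision_time
            else:
                ss = np.random.SeedSequence([grid.seed, i, j])
                es = simulate_ensemble(
                    env, policy, grid.n_trials, np.random.default_rng(ss), grid.t_max
                )
                truncated = es.n_truncated / es.n_trials
                valid = es.n_truncated == 0
                p_c, dt = es.p_correct, es.mean_decision_time
            rows.append((theta, phi, p_c, dt, truncated, valid))
    return pd.DataFrame(
        rows, columns=["theta", "phi", "p_correct", "mean_dt", "truncated", "valid"]
    )


def attach_fitness(
    perf: pd.DataFrame, benefit: float, c_time: float, k: float
) -> pd.DataFrame:
    """Price a performance table at a given benefit, time cost and effort curve."""
    out = perf.copy()
    phi = out["phi"].to_numpy()
    c_eff = k * phi / (1.0 - phi)
    out["c_effort"] = c_eff
    out["fitness"] = fitness(
        out["p_correct"].to_numpy(), out["mean_dt"].to_numpy(), benefit, c_time, c_eff
    )
    return out[LANDSCAPE_COLUMNS + ["truncated"]]


def evaluate_landscape(
    env: EnvironmentParams,
    costs: EffortCostParams,
    grid: GridSpec,
    c_time: float | None = None,
    perf: pd.DataFrame | None = None,
) -> Landscape:
    """Evaluate fitness over the whole grid.

    ``c_time`` defaults to the environment's baseline; pass ``perf`` (a
    precomputed :func:`performance_table`) to re-price an existing grid at
    a different time cost without re-evaluating it.
    """
    ct = env.c_time if c_time is None else float(c_time)
    if ct < 0:
        raise ValueError(f"c_time must be >= 0, got {ct}")
    if perf is None:
        perf = performance_table(env, grid)
    cells = attach_fitness(perf, env.benefit, ct, costs.k)
    n_invalid = int((~cells["valid"]).sum())
    if n_invalid == len(cells):
        raise ValueError(
            "all landscape cells are invalid (truncated); "
            "increase t_max or restrict the grid"
        )
    if n_invalid:
        logger.info("landscape: %d of %d cells invalid (truncated)", n_invalid, len(cells))
    return Landscape(cells=cells, env=env, costs=costs, grid=grid, c_time=ct)


def optimal_cell(landscape: Landscape) -> pd.Series:
    """Row of the best valid cell; exact ties broken by smallest theta, then phi.

    Exact fitness ties are common in oracle mode: the absorption pattern,
    hence P_C and DT, is piecewise-constant in theta between lattice
    crossings, so whole theta-runs of cells share one fitness value.
    """
    valid = landscape.cells[landscape.cells["valid"]]
    if valid.empty:
        raise ValueError("landscape has no valid cells")
    w_max = valid["fitness"].max()
    tied = valid[valid["fitness"] == w_max]
    if len(tied) > 1:
        logger.info(
            "optimum tie among %d cells at W=%r; lexicographic tie-break (theta, phi)",
            len(tied),
            w_max,
        )
    return tied.sort_values(["theta", "phi"]).iloc[0]


def find_optimum(landscape: Landscape) -> Optimum:
    """The (theta*, phi*) pair attaining the maximum fitness over valid cells."""
    cell = optimal_cell(landscape)
    return Optimum(float(cell["theta"]), float(cell["phi"]))


def _prominence_merges(w: np.ndarray, valid: np.ndarray) -> list[float]:
    """Topographic prominences of non-global local maxima (H0 persistence).

    Cells are activated in decreasing fitness order and unioned with active
    4-neighbors; when two components merge, the lower-summit component dies
    and its prominence is summit minus the merge level.  Plateau cells join
    existing components at zero prominence, so plateaus are merged for free.
    """
    nr, nc = w.shape
    flat = np.where(valid, w, -np.inf).ravel()
    order = np.argsort(flat, kind="stable")[::-1][: int(valid.sum())]
    parent = np.full(nr * nc, -1, dtype=np.int64)
    summit = np.full(nr * nc, -np.inf)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    merges: list[float] = []
    for idx in order:
        r, c = divmod(int(idx), nc)
        parent[idx] = idx
        summit[idx] = w[r, c]
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and parent[rr * nc + cc] != -1:
                a, b = find(int(idx)), find(rr * nc + cc)
                if a != b:
                    if summit[a] < summit[b]:
                        a, b = b, a
                    merges.append(float(summit[b] - w[r, c]))
                    parent[b] = a
    return sorted(merges, reverse=True)


def is_single_peaked(
    landscape: Landscape, min_prominence: float | None = None
) -> tuple[bool, dict]:
    """Does the landscape have a single (macroscopic) maximum?

    Exact oracle evaluation resolves the quantization of the evidence
    lattice: fitness is terraced in theta and rippled in phi, producing
    many micro-maxima whose topographic prominence is orders of magnitude
    below the landscape relief.  A maximum therefore counts as a peak only
    if its prominence exceeds ``min_prominence``; the default is 1% of the
    fitness range over valid cells, far above the quantization ripple and
    far below any genuine second mode.  Pass ``min_prominence=0`` for the
    raw plateau-merged local-maximum count.

    Returns ``(flag, diagnostics)`` with the peak count, the prominence
    spectrum, and the threshold used.
    """
    w = landscape.fitness_matrix()
    valid = landscape.valid_matrix()
    if not valid.any():
        raise ValueError("landscape has no valid cells")
    merges = _prominence_merges(w, valid)
    relief = float(w[valid].max() - w[valid].min())
    if min_prominence is None:
        min_prominence = 0.01 * relief
    n_peaks = 1 + sum(1 for p in merges if p > min_prominence)
    diagnostics = {
        "n_peaks": n_peaks,
        "n_local_maxima_raw": 1 + sum(1 for p in merges if p > 0.0),
        "prominences": merges[:20],
        "min_prominence": float(min_prominence),
        "fitness_relief": relief,
    }
    return n_peaks == 1, diagnostics


def write_landscape(landscape: Landscape, path) -> None:
    """Write the cell table as tab-delimited text (header, LF, full precision)."""
    cells = landscape.cells[LANDSCAPE_COLUMNS]
    cells.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.17g")
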