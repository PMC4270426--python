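"""Fitness landscapes: pricing, optimization, peak structure, output format."""

import math

import numpy as np
import pandas as pd
import pytest

from speedeffort import (
    EffortCostParams,
    EnvironmentParams,
    GridSpec,
    Landscape,
    Policy,
    evaluate_landscape,
    find_optimum,
    fitness,
    is_single_peaked,
    optimal_cell,
    simulate_ensemble,
    write_landscape,
)
from speedeffort.landscape import LANDSCAPE_COLUMNS, attach_fitness, performance_table
from speedeffort.oracle import decision_time_moments, oracle_summary

SMALL_ENV = EnvironmentParams(0.75, 0.25, benefit=100.0, c_time=0.2)
COSTS = EffortCostParams(k=0.2)


def small_grid(mode="oracle", seed=0, n_trials=2_000):
    return GridSpec(
        theta_values=(0.7, 0.8, 0.9),
        phi_values=(0.4, 0.6, 0.8),
        n_trials=n_trials,
        t_max=5_000,
        seed=seed,
        mode=mode,
    )


def synthetic_landscape(w: np.ndarray, valid: np.ndarray | None = None) -> Landscape:
    """Wrap a fitness matrix in a Landscape for peak-structure tests."""
    nr, nc = w.shape
    thetas = np.linspace(0.6, 0.9, nr)
    phis = np.linspace(0.1, 0.9, nc)
    if valid is None:
        valid = np.ones_like(w, dtype=bool)
    rows = []
    for i in range(nr):
        for j in range(nc):
            rows.append((thetas[i], phis[j], 0.5, 1.0, 0.0, w[i, j], bool(valid[i, j])))
    cells = pd.DataFrame(rows, columns=LANDSCAPE_COLUMNS)
    grid = GridSpec(theta_values=tuple(thetas), phi_values=tuple(phis))
    return Landscape(cells=cells, env=SMALL_ENV, costs=COSTS, grid=grid, c_time=0.2)


class TestFitness:
    @pytest.mark.parametrize(
        "p, dt, b, ct, ce, expected",
        [
            (1.0, 1.0, 10.0, 1.0, 1.0, 8.0),
            (0.9, 3.2, 10.0, 0.5, 0.5, 5.8),
        ],
    )
    def test_values(self, p, dt, b, ct, ce, expected):
        assert fitness(p, dt, b, ct, ce) == pytest.approx(expected)

    def test_zero_benefit_never_positive(self):
        for p in (0.0, 0.5, 1.0):
            for dt in (1.0, 5.0):
                assert fitness(p, dt, 0.0, 0.1, 0.2) <= 0.0


class TestGridSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(theta_values=(0.8, 0.7)),  # not increasing
            dict(theta_values=(0.4, 0.8)),  # below 0.5
            dict(phi_values=(0.2, 1.0)),  # phi = 1 excluded
            dict(n_trials=0),
            dict(mode="exact"),
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            GridSpec(**kwargs)

    def test_default_shape(self):
        grid = GridSpec()
        assert grid.shape == (45, 50)
        assert grid.theta_values[0] == 0.55 and grid.theta_values[-1] == 0.99
        assert grid.phi_values[0] == 0.0 and grid.phi_values[-1] == 0.98


class TestEvaluateLandscape:
    def test_single_cell_oracle_equals_summary(self):
        grid = GridSpec(theta_values=(0.85,), phi_values=(0.6,), mode="oracle")
        scape = evaluate_landscape(SMALL_ENV, COSTS, grid)
        cell = scape.cells.iloc[0]
        o = oracle_summary(SMALL_ENV, Policy(0.85, 0.6))
        assert cell["p_correct"] == pytest.approx(o.p_correct, abs=1e-12)
        assert cell["mean_dt"] == pytest.approx(o.mean_decision_time, abs=1e-10)
        ce = COSTS.k * 0.6 / 0.4
        assert cell["fitness"] == pytest.approx(
            fitness(o.p_correct, o.mean_decision_time, 100.0, 0.2, ce), rel=1e-12
        )

    def test_single_cell_simulate_equals_ensemble(self):
        grid = GridSpec(
            theta_values=(0.85,), phi_values=(0.6,), n_trials=500, seed=9, mode="simulate"
        )
        scape = evaluate_landscape(SMALL_ENV, COSTS, grid)
        cell = scape.cells.iloc[0]
        ss = np.random.SeedSequence([9, 0, 0])
        ref = simulate_ensemble(
            SMALL_ENV, Policy(0.85, 0.6), 500, np.random.default_rng(ss), grid.t_max
        )
        assert cell["p_correct"] == ref.p_correct
        assert cell["mean_dt"] == ref.mean_decision_time

    def test_simulate_mode_deterministic(self):
        a = evaluate_landscape(SMALL_ENV, COSTS, small_grid("simulate", seed=4))
        b = evaluate_landscape(SMALL_ENV, COSTS, small_grid("simulate", seed=4))
        pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_oracle_and_simulate_agree(self):
        """Cell-wise agreement within 3 Monte-Carlo standard errors."""
        n = 10_000
        grid_sim = GridSpec(
            theta_values=(0.7, 0.75, 0.8, 0.85, 0.9),
            phi_values=(0.3, 0.45, 0.6, 0.75, 0.9),
            n_trials=n,
            seed=21,
            mode="simulate",
        )
        sim = evaluate_landscape(SMALL_ENV, COSTS, grid_sim)
        for _, row in sim.cells.iterrows():
            policy = Policy(row["theta"], row["phi"])
            o = oracle_summary(SMALL_ENV, policy)
            se_p = math.sqrt(max(o.p_correct * (1 - o.p_correct), 1e-12) / n)
            _, var_t = decision_time_moments(SMALL_ENV, policy)
            se_t = math.sqrt(max(var_t, 0.0) / n)
            # +1e-9 absorbs cells whose decision time is deterministic
            assert abs(row["p_correct"] - o.p_correct) < 3.5 * se_p + 1e-9
            assert abs(row["mean_dt"] - o.mean_decision_time) < 3.5 * se_t + 1e-9

    def test_all_invalid_raises(self):
        grid = GridSpec(theta_values=(0.9,), phi_values=(0.0,), t_max=100)
        with pytest.raises(ValueError, match="invalid"):
            evaluate_landscape(SMALL_ENV, COSTS, grid)

    def test_valid_cells_have_finite_fitness(self, default_env, default_costs, default_grid, default_perf):
        scape = evaluate_landscape(default_env, default_costs, default_grid, perf=default_perf)
        valid = scape.cells[scape.cells["valid"]]
        assert np.isfinite(valid["fitness"]).all()
        assert len(scape.cells) == 45 * 50


class TestFindOptimum:
    def test_unique_maximum(self):
        w = np.array([[1.0, 2.0], [3.0, 4.0]])
        scape = synthetic_landscape(w)
        cell = optimal_cell(scape)
        assert cell["fitness"] == 4.0

    def test_tie_break_lexicographic(self):
        w = np.array([[1.0, 5.0], [5.0, 0.0]])
        scape = synthetic_landscape(w)
        opt = find_optimum(scape)
        # both 5.0 cells tie; smallest theta wins, then smallest phi
        assert opt.theta_star == pytest.approx(scape.grid.theta_values[0])
        assert opt.phi_star == pytest.approx(scape.grid.phi_values[1])

    def test_invalid_cells_excluded(self):
        w = np.array([[9.0, 1.0], [2.0, 3.0]])
        valid = np.array([[False, True], [True, True]])
        scape = synthetic_landscape(w, valid)
        assert optimal_cell(scape)["fitness"] == 3.0

    def test_matches_brute_force_on_default_landscape(
        self, default_env, default_costs, default_grid, default_perf
    ):
        scape = evaluate_landscape(default_env, default_costs, default_grid, perf=default_perf)
        opt = find_optimum(scape)
        # independent scan over the table rows
        best = None
        for row in scape.cells.itertuples():
            if not row.valid:
                continue
            key = (-row.fitness, row.theta, row.phi)
            if best is None or key < best:
                best = key
        assert (opt.theta_star, opt.phi_star) == (best[1], best[2])


class TestSinglePeaked:
    def test_concave_surface(self):
        x = np.linspace(-1, 1, 12)
        y = np.linspace(-1, 1, 15)
        w = -(x[:, None] ** 2 + y[None, :] ** 2)
        ok, diag = is_single_peaked(synthetic_landscape(w))
        assert ok and diag["n_peaks"] == 1

    def test_two_bumps(self):
        x = np.linspace(-1, 1, 21)
        w = np.exp(-((x[:, None] + 0.6) ** 2 + (x[None, :] + 0.6) ** 2) / 0.05)
        w += np.exp(-((x[:, None] - 0.6) ** 2 + (x[None, :] - 0.6) ** 2) / 0.05)
        ok, diag = is_single_peaked(synthetic_landscape(w))
        assert not ok and diag["n_peaks"] == 2

    def test_plateau_counts_once(self):
        w = np.zeros((5, 5))
        w[1:4, 1:4] = 1.0  # flat top
        ok, diag = is_single_peaked(synthetic_landscape(w))
        assert ok and diag["n_local_maxima_raw"] == 1

    def test_quantization_ripple_is_ignored(self):
        """Micro-maxima far below the relief do not count as peaks."""
        x = np.linspace(-1, 1, 30)
        w = -(x[:, None] ** 2 + x[None, :] ** 2) * 10.0
        # tiny ripple poking just above its 4-neighborhood
        w[5, 5] = max(w[4, 5], w[6, 5], w[5, 4], w[5, 6]) + 1e-3
        ok, diag = is_single_peaked(synthetic_landscape(w))
        assert ok
        assert diag["n_local_maxima_raw"] == 2  # the ripple is a raw maximum


class TestOutput:
    def test_write_landscape_format(self, tmp_path):
        scape = evaluate_landscape(SMALL_ENV, COSTS, small_grid("oracle"))
        path = tmp_path / "landscape.tsv"
        write_landscape(scape, path)
        raw = path.read_bytes()
        assert b"\r" not in raw
        lines = raw.decode().splitlines()
        assert lines[0].split("\t") == LANDSCAPE_COLUMNS
        assert len(lines) == 1 + 9
        back = pd.read_csv(path, sep="\t")
        assert back["fitness"].to_numpy() == pytest.approx(
            scape.cells["fitness"].to_numpy(), rel=1e-15
        )

    def test_repricing_equals_direct_evaluation(self):
        """attach_fitness on a cached performance table matches a fresh run."""
        perf = performance_table(SMALL_ENV, small_grid("oracle"))
        direct = evaluate_landscape(SMALL_ENV, COSTS, small_grid("oracle"), c_time=0.7)
        cached = attach_fitness(perf, SMALL_ENV.benefit, 0.7, COSTS.k)
        assert cached["fitness"].to_numpy() == pytest.approx(
            direct.cells["fitness"].to_numpy(), rel=1e-15
        )
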