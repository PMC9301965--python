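import numpy as np
import pandas as pd
import pytest

from sensopt import (
    BoostParams,
    SensorGrid,
    SimulationConfig,
    generate,
    greedy_stack,
    optimal_count,
    pareto_knees,
    rank_first_node,
)
from sensopt.selection import SelectionResult, rmse_reductions

FAST = BoostParams(n_estimators=30, learning_rate=0.3, max_depth=2)


def result_from_curve(curve):
    n = len(curve)
    return SelectionResult(
        ranked_nodes=[f"N{i}" for i in range(n)],
        cumulative_rmse=list(curve),
        variable_set="raw",
        target_node="N0",
    )


def duplicated_node_matrix(n_rows=120):
    """Two nodes with byte-identical readings (plus a third distinct one)."""
    rng = np.random.default_rng(0)
    t = np.arange(n_rows)
    x = 20 + 5 * np.sin(2 * np.pi * t / 48) + rng.normal(0, 0.5, n_rows)
    rh = 60 - 2 * (x - 20) + rng.normal(0, 1.0, n_rows)
    other = 20 + rng.normal(0, 3.0, n_rows)
    return pd.DataFrame(
        {
            "timestamp": pd.date_range("2022-03-01", periods=n_rows, freq="30min"),
            "A1_T": x, "A1_RH": rh,
            "A2_T": x, "A2_RH": rh,
            "A3_T": other, "A3_RH": rh + rng.normal(0, 1.0, n_rows),
        }
    )


class TestRankFirstNode:
    def test_identical_nodes_tie_breaks_to_grid_order(self):
        m = duplicated_node_matrix()
        node, _ = rank_first_node(m, ["A1", "A2", "A3"], params=FAST)
        assert node == "A1"
        # grid order is whatever order the candidate list carries
        node_rev, _ = rank_first_node(m, ["A2", "A1", "A3"], params=FAST)
        assert node_rev == "A2"

    def test_planted_low_noise_node_wins(self):
        grid = SensorGrid(columns=("A",), rows=(1, 2, 3, 4, 5))
        cfg = SimulationConfig(
            n_days=5, sampling_interval=30, rng_seed=4,
            sensor_noise_sd_temp=4.5, sensor_noise_sd_rh=8.0,
            field_sd=0.5, temporal_corr_minutes=30.0,
            informative_nodes=["A3"], informative_noise_factor=0.2,
            missing_fraction=0.0,
        )
        m = generate(grid, cfg)
        node, score = rank_first_node(m, grid.nodes, params=FAST)
        assert node == "A3"
        assert score > 0

    def test_fewer_than_two_nodes_rejected(self):
        m = duplicated_node_matrix()
        with pytest.raises(ValueError):
            rank_first_node(m, ["A1"], params=FAST)

    def test_missing_values_rejected(self):
        m = duplicated_node_matrix()
        m.loc[3, "A1_T"] = np.nan
        with pytest.raises(ValueError, match="preprocessing"):
            rank_first_node(m, ["A1", "A2"], params=FAST)


class TestGreedyStack:
    def test_single_node_equals_rank_first(self, small_matrix, small_grid):
        result = greedy_stack(small_matrix, small_grid.nodes, params=FAST, max_nodes=1)
        node, score = rank_first_node(small_matrix, small_grid.nodes, params=FAST)
        assert result.ranked_nodes == [node]
        assert result.cumulative_rmse == [score]

    def test_curve_length_and_distinct_ranking(self, small_matrix, small_grid):
        result = greedy_stack(small_matrix, small_grid.nodes, params=FAST, max_nodes=3)
        assert len(result.cumulative_rmse) == 3
        assert len(set(result.ranked_nodes)) == 3
        # the recorded value at each step is the minimum over its candidates
        for step, scores in enumerate(result.history):
            assert result.cumulative_rmse[step] == min(scores.values())

    def test_excess_max_nodes_clipped_with_warning(self, small_matrix, small_grid):
        with pytest.warns(UserWarning, match="clipping"):
            result = greedy_stack(
                small_matrix, small_grid.nodes, params=FAST, max_nodes=99
            )
        assert len(result.ranked_nodes) == len(small_grid.nodes)

    def test_ranking_invariant_to_input_column_order(self, small_matrix, small_grid):
        shuffled_cols = ["timestamp"] + [
            c for c in reversed(small_matrix.columns) if c != "timestamp"
        ]
        shuffled = small_matrix[shuffled_cols]
        a = greedy_stack(small_matrix, small_grid.nodes, params=FAST, max_nodes=3)
        b = greedy_stack(shuffled, small_grid.nodes, params=FAST, max_nodes=3)
        assert a.ranked_nodes == b.ranked_nodes
        assert a.cumulative_rmse == b.cumulative_rmse


class TestOptimalCount:
    def test_minimum_before_sustained_rise(self):
        # curve shape with the optimum at the 4th sensor set
        curve = [0.0448124, 0.0133850, 0.0114320, 0.0102077, 0.0108046, 0.0110145]
        assert optimal_count(result_from_curve(curve)) == 4

    def test_early_minimum_despite_later_points(self):
        curve = [0.0397534, 0.0355036, 0.0373681, 0.0381142]
        assert optimal_count(result_from_curve(curve)) == 2

    def test_strictly_decreasing_curve_uses_all_sensors(self):
        curve = [0.5, 0.4, 0.3, 0.2]
        assert optimal_count(result_from_curve(curve)) == 4

    def test_tie_takes_earliest(self):
        assert optimal_count(result_from_curve([0.3, 0.2, 0.2, 0.3])) == 2

    def test_optimal_rmse_is_curve_minimum(self):
        curve = [0.05, 0.01, 0.02, 0.03]
        res = result_from_curve(curve)
        k = optimal_count(res)
        assert curve[k - 1] == min(curve)

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            optimal_count(result_from_curve([]))


class TestParetoKnees:
    def test_reductions_match_brute_force(self):
        curve = [0.08, 0.05, 0.045, 0.02, 0.019]
        red = rmse_reductions(result_from_curve(curve))
        for i in range(len(curve) - 1):
            assert red[i] == pytest.approx(
                100.0 * (curve[i] - curve[i + 1]) / curve[i], rel=1e-12
            )

    def test_first_drop_of_steep_curve_is_a_knee(self):
        curve = [0.0448124, 0.0133850, 0.0114320, 0.0102077, 0.0108046]
        knees = pareto_knees(result_from_curve(curve))
        assert knees[0][0] == 0
        assert knees[0][1] == pytest.approx(70.13, abs=0.01)

    def test_flat_curve_has_no_knees(self):
        assert pareto_knees(result_from_curve([0.05, 0.05, 0.05, 0.05])) == []

    def test_threshold_filters_small_drops(self):
        curve = [0.10, 0.095, 0.09, 0.089]
        assert pareto_knees(result_from_curve(curve), threshold=10.0) == []
        assert len(pareto_knees(result_from_curve(curve), threshold=1.0)) >= 1

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            pareto_knees(result_from_curve([0.2, 0.1]))
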