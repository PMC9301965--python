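"""Canned validation experiments on synthetic microclimate data.

These define the package's standard self-checks:

* **Planted recovery** — a 16-node greenhouse with three planted informative
  sensors (one at the air-loop mixing chamber, two at conditioning units
  driving it) among thirteen ordinary drifting sensors.  A correct greedy
  ranking should place the planted trio first and stop adding sensors soon
  after.
* **Greedy-step optimality** — an 8-node instance small enough to verify,
  by exhaustive re-evaluation, that every greedy addition was the best
  available candidate.

Problem sizes (30 simulated days at 30-minute sampling, 150-stage depth-2
boosting) are chosen so a full 20-seed recovery study runs in minutes on one
CPU while leaving clear separation between planted and ordinary sensors.
"""

from __future__ import annotations

from dataclasses import dataclass

from .forecast_eval import BoostParams
from .grid import SensorGrid
from .node_model import target_column
from .preprocess import SplitSpec
from .selection import SelectionResult, greedy_stack, optimal_count
from .synthetic import SimulationConfig, generate

#: 4 x 4 node grid used by the recovery experiment.
RECOVERY_GRID = SensorGrid(columns=("A", "B", "C", "D"), rows=(1, 2, 3, 4))

#: Planted informative sensors: mixing chamber first, then the two units.
RECOVERY_PLANTED = ["B2", "C3", "B3"]

#: Forecaster settings for the experiments: converged (high learning rate,
#: enough stages) so that adding irrelevant sensors cannot help by merely
#: accelerating an underfit model.
EXPERIMENT_BOOST = BoostParams(n_estimators=150, learning_rate=0.3, max_depth=2)


def recovery_config(seed: int) -> SimulationConfig:
    """Study conditions for one recovery run.

    Ordinary sensors: noise sd 4.5 degC / 8 %RH, degrading (noise triples
    over the window).  Planted sensors: stable, noise scaled by 0.2 (5x
    ratio).  The disturbance sources are moderately persistent (30 min) with
    coupling 0.5 from the units into the mixing chamber.
    """
    return SimulationConfig(
        n_days=30,
        sampling_interval=30,
        rng_seed=seed,
        sensor_noise_sd_temp=4.5,
        sensor_noise_sd_rh=8.0,
        field_sd=0.5,
        temporal_corr_minutes=30.0,
        spatial_correlation_length=3.0,
        source_sd=3.5,
        source_corr_minutes=30.0,
        source_coupling=0.5,
        noise_drift=2.0,
        informative_nodes=list(RECOVERY_PLANTED),
        informative_noise_factor=0.2,
        missing_fraction=0.0,
    )


@dataclass
class RecoveryRun:
    seed: int
    result: SelectionResult
    top3_recovered: bool
    optimal_count: int


def run_recovery(seed: int, max_nodes: int = 6) -> RecoveryRun:
    """Generate one recovery dataset and run the greedy selection on it."""
    matrix = generate(RECOVERY_GRID, recovery_config(seed))
    result = greedy_stack(
        matrix,
        RECOVERY_GRID.nodes,
        variable_set="raw",
        params=EXPERIMENT_BOOST,
        max_nodes=max_nodes,
    )
    return RecoveryRun(
        seed=seed,
        result=result,
        top3_recovered=set(result.ranked_nodes[:3]) == set(RECOVERY_PLANTED),
        optimal_count=optimal_count(result),
    )


def recovery_rates(seeds) -> tuple[float, float, list[RecoveryRun]]:
    """Fraction of runs recovering the planted trio / stopping by 5 sensors."""
    runs = [run_recovery(s) for s in seeds]
    n = len(runs)
    top3 = sum(r.top3_recovered for r in runs) / n
    count = sum(r.optimal_count <= 5 for r in runs) / n
    return top3, count, runs


#: 8-node grid for the greedy-step optimality check.
ORACLE_GRID = SensorGrid(columns=("A", "B"), rows=(1, 2, 3, 4))


def oracle_config(seed: int) -> SimulationConfig:
    """Small instance with two planted sensors for greedy-step verification."""
    return SimulationConfig(
        n_days=10,
        sampling_interval=30,
        rng_seed=seed,
        sensor_noise_sd_temp=4.5,
        sensor_noise_sd_rh=8.0,
        field_sd=0.5,
        temporal_corr_minutes=30.0,
        spatial_correlation_length=3.0,
        source_sd=3.5,
        source_corr_minutes=30.0,
        source_coupling=0.5,
        noise_drift=2.0,
        informative_nodes=["A2", "B3"],
        informative_noise_factor=0.2,
        missing_fraction=0.0,
    )


def greedy_step_gaps(seed: int, params: BoostParams | None = None) -> list[float]:
    """Worst margin (rejected minus chosen RMSE) per greedy step, 8 nodes.

    Re-evaluates every candidate at every iteration independently of the
    greedy run and returns ``min(rejected) - chosen`` for each step; all
    values must be >= 0 if each greedy addition was optimal.
    """
    from .selection import _fit_rmse  # independent per-candidate refits

    params = params or EXPERIMENT_BOOST
    matrix = generate(ORACLE_GRID, oracle_config(seed))
    nodes = ORACLE_GRID.nodes
    result = greedy_stack(matrix, nodes, params=params, max_nodes=len(nodes))
    target_col = target_column(result.target_node, "raw")
    split = SplitSpec()

    gaps: list[float] = []
    for step in range(1, len(result.ranked_nodes)):
        selected = result.ranked_nodes[:step]
        chosen = result.ranked_nodes[step]
        chosen_rmse = result.cumulative_rmse[step]
        others = [
            _fit_rmse(matrix, selected + [c], target_col, "raw", 1, params, split)
            for c in nodes
            if c not in selected and c != chosen
        ]
        if others:  # the final step has no rejected alternatives
            gaps.append(min(others) - chosen_rmse)
    return gaps
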