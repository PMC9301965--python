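"""Greedy forward ranking of sensor locations by validation RMSE.

The placement method has two stages.  First, every candidate location is
scored by how well a boosted-tree model forecasts that location's own reading
one step ahead from its contemporaneous variables plus calendar features; the
location with the lowest validation RMSE becomes the anchor.  Second, the
anchor's one-step-ahead reading is fixed as the target, and locations are
appended greedily: at every iteration the candidate whose variables, added to
the growing feature set, yield the lowest validation RMSE joins the ranking.
The cumulative RMSE curve over the ranking determines the optimal sensor
count (its earliest global minimum — the point beyond which adding sensors no
longer reduces the error) and the knee points of the count-vs-error Pareto
front.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forecast_eval import BoostParams, fit_boosted
from .node_model import (
    NodeSubmatrix,
    assemble_nodes,
    make_supervised,
    node_columns,
    target_column,
)
from .preprocess import SplitSpec


@dataclass
class SelectionResult:
    """Ranked sensor locations with the cumulative validation-RMSE curve.

    ``ranked_nodes[i]`` is the (i+1)-th location added; ``cumulative_rmse[i]``
    is the validation RMSE of the model using the first i+1 locations.
    ``history[i]`` maps every candidate evaluated at step i to its RMSE.
    """

    ranked_nodes: list[str]
    cumulative_rmse: list[float]
    variable_set: str
    target_node: str
    k: int = 1
    history: list[dict[str, float]] = field(default_factory=list)

    @property
    def optimal_count(self) -> int:
        return optimal_count(self)

    def to_frame(self) -> pd.DataFrame:
        """Ranking table: index, cumulative sensor list, RMSE."""
        return pd.DataFrame(
            {
                "index": range(len(self.ranked_nodes)),
                "sensor_locations": [
                    ", ".join(self.ranked_nodes[: i + 1])
                    for i in range(len(self.ranked_nodes))
                ],
                "rmse": self.cumulative_rmse,
            }
        )


def _check_matrix(matrix: pd.DataFrame, nodes: list[str], variable_set: str) -> None:
    cols = [c for n in nodes for c in node_columns(n, variable_set)]
    missing = [c for c in cols if c not in matrix.columns]
    if missing:
        raise KeyError(f"matrix lacks columns for the requested nodes: {missing[:5]}")
    if matrix[cols].isna().any().any():
        raise ValueError("matrix contains missing values; run preprocessing first")


def _supervised_from_columns(
    matrix: pd.DataFrame,
    feature_nodes: list[str],
    target_col: str,
    variable_set: str,
    k: int,
) -> "NodeSubmatrix":
    data = assemble_nodes(matrix, feature_nodes, variable_set)
    if target_col not in data.columns:
        data = pd.concat([data, matrix[[target_col]]], axis=1)
    return NodeSubmatrix(
        node_id=feature_nodes[0],
        data=data,
        timestamps=pd.to_datetime(matrix["timestamp"]).reset_index(drop=True),
    )


def _fit_rmse(
    matrix: pd.DataFrame,
    feature_nodes: list[str],
    target_col: str,
    variable_set: str,
    k: int,
    params: BoostParams,
    split: SplitSpec,
) -> float:
    sub = _supervised_from_columns(matrix, feature_nodes, target_col, variable_set, k)
    frame = make_supervised(sub, target_variable=target_col, k=k)
    # the target's contemporaneous value stays among the features (the node's
    # own present reading is its best single predictor one step ahead)
    return fit_boosted(frame, params, split=split).val_rmse


def score_all_nodes(
    matrix: pd.DataFrame,
    nodes: list[str],
    variable_set: str = "raw",
    params: BoostParams = BoostParams(),
    split: SplitSpec = SplitSpec(),
    k: int = 1,
) -> dict[str, float]:
    """Validation RMSE of a self-forecast model at every candidate location."""
    _check_matrix(matrix, nodes, variable_set)
    scores = {}
    for n in nodes:
        scores[n] = _fit_rmse(
            matrix, [n], target_column(n, variable_set), variable_set, k, params, split
        )
    return scores


def rank_first_node(
    matrix: pd.DataFrame,
    nodes: list[str],
    variable_set: str = "raw",
    params: BoostParams = BoostParams(),
    split: SplitSpec = SplitSpec(),
    k: int = 1,
) -> tuple[str, float]:
    """Exhaustively score all locations; return the best (lowest val RMSE).

    Ties break toward the earliest node in grid order (the order of
    ``nodes``).
    """
    if len(nodes) < 2:
        raise ValueError("need at least 2 candidate nodes to rank")
    scores = score_all_nodes(matrix, nodes, variable_set, params, split, k)
    best = min(nodes, key=lambda n: scores[n])  # min is stable: first wins ties
    return best, scores[best]


def greedy_stack(
    matrix: pd.DataFrame,
    nodes: list[str],
    variable_set: str = "raw",
    params: BoostParams = BoostParams(),
    split: SplitSpec = SplitSpec(),
    k: int = 1,
    max_nodes: int | None = None,
) -> SelectionResult:
    """Greedy forward selection of sensor locations.

    The first location is chosen by :func:`rank_first_node`; its one-step
    forecast becomes the fixed target.  Each further iteration appends the
    candidate minimizing validation RMSE when its variables join the feature
    set, recording the cumulative RMSE curve.
    """
    if max_nodes is None:
        max_nodes = len(nodes)
    elif max_nodes > len(nodes):
        warnings.warn(
            f"max_nodes={max_nodes} exceeds the {len(nodes)} available nodes; clipping",
            stacklevel=2,
        )
        max_nodes = len(nodes)
    if max_nodes < 1:
        raise ValueError("max_nodes must be >= 1")

    scores = score_all_nodes(matrix, nodes, variable_set, params, split, k)
    first = min(nodes, key=lambda n: scores[n])
    target_col = target_column(first, variable_set)

    selected = [first]
    curve = [scores[first]]
    history = [dict(scores)]

    while len(selected) < max_nodes:
        candidates = [n for n in nodes if n not in selected]
        step_scores = {}
        for c in candidates:
            step_scores[c] = _fit_rmse(
                matrix, selected + [c], target_col, variable_set, k, params, split
            )
        best = min(candidates, key=lambda n: step_scores[n])
        selected.append(best)
        curve.append(step_scores[best])
        history.append(step_scores)

    return SelectionResult(
        ranked_nodes=selected,
        cumulative_rmse=curve,
        variable_set=variable_set,
        target_node=first,
        k=k,
        history=history,
    )


def optimal_count(result: SelectionResult) -> int:
    """Number of sensors at the earliest global minimum of the RMSE curve.

    Beyond this point adding sensors no longer reduces the validation error;
    the curve may dip non-monotonically before the optimum, so the global
    minimum (not the first local rise) defines it.
    """
    curve = np.asarray(result.cumulative_rmse, dtype=float)
    if curve.size == 0:
        raise ValueError("empty RMSE curve")
    return int(np.argmin(curve)) + 1  # argmin returns the earliest minimum


def rmse_reductions(result: SelectionResult) -> np.ndarray:
    """Consecutive relative RMSE reductions, percent: 100 (r_i - r_{i+1}) / r_i."""
    curve = np.asarray(result.cumulative_rmse, dtype=float)
    return 100.0 * (curve[:-1] - curve[1:]) / curve[:-1]


def pareto_knees(
    result: SelectionResult, threshold: float = 10.0
) -> list[tuple[int, float]]:
    """Knee points of the sensor-count vs RMSE trade-off curve.

    Returns ``(i, pct)`` pairs where ``pct`` is the relative RMSE reduction
    between ``cumulative_rmse[i]`` and ``cumulative_rmse[i+1]`` (i.e. between
    i+1 and i+2 sensors), restricted to local maxima of the reduction series
    that exceed ``threshold`` percent.
    """
    if len(result.cumulative_rmse) < 3:
        raise ValueError("need at least 3 points on the curve for knee analysis")
    red = rmse_reductions(result)
    knees = []
    for i, r in enumerate(red):
        if r < threshold:
            continue
        left = red[i - 1] if i > 0 else -np.inf
        right = red[i + 1] if i < len(red) - 1 else -np.inf
        if r >= left and r >= right:
            knees.append((i, float(r)))
    return knees
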