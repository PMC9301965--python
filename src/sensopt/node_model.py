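"""Per-node submatrices and supervised one-step-ahead forecasting frames.

Each 2-in-1 sensor node contributes a contiguous block of columns to the full
observation matrix (temperature and relative humidity for raw data; one
column per derived psychrometric property otherwise).  A supervised frame
pairs the contemporaneous node variables — plus engineered calendar features
of the timestamp — with the target variable shifted ``k`` sampling steps into
the future.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Variable sets and their per-node column suffixes.
VARIABLE_SETS: dict[str, tuple[str, ...]] = {
    "raw": ("T", "RH"),
    "T": ("T", "RH"),
    "RH": ("T", "RH"),
    "Td": ("Td",),
    "w": ("w",),
    "h": ("h",),
    "v": ("v",),
}

#: Calendar features engineered from the timestamp, encoded as integers.
TIME_FEATURES = ("hour", "day_of_month", "day_of_week", "month")


@dataclass
class NodeSubmatrix:
    """One node's block of the observation matrix, row count preserved."""

    node_id: str
    data: pd.DataFrame  # the node's variable columns, in matrix order
    timestamps: pd.Series


@dataclass
class SupervisedFrame:
    """Feature block X and k-step-ahead target y, aligned row-for-row."""

    X: pd.DataFrame
    y: pd.Series
    k: int
    target_name: str


def node_columns(node_id: str, variable_set: str = "raw") -> list[str]:
    """Column names a node contributes under the given variable set."""
    try:
        suffixes = VARIABLE_SETS[variable_set]
    except KeyError:
        raise ValueError(
            f"unknown variable set {variable_set!r}; expected one of "
            f"{sorted(set(VARIABLE_SETS))}"
        ) from None
    return [f"{node_id}_{s}" for s in suffixes]


def target_column(node_id: str, variable_set: str = "raw") -> str:
    """The column forecast as the target for a node under a variable set.

    Raw data defaults to temperature; ``"RH"`` selects humidity; each
    psychrometric set forecasts its own property.
    """
    if variable_set in ("raw", "T"):
        return f"{node_id}_T"
    if variable_set == "RH":
        return f"{node_id}_RH"
    return f"{node_id}_{variable_set}"


def extract_node(
    matrix: pd.DataFrame, node_id: str, variable_set: str = "raw"
) -> NodeSubmatrix:
    """Pull one node's variable columns out of the full observation matrix."""
    cols = node_columns(node_id, variable_set)
    missing = [c for c in cols if c not in matrix.columns]
    if missing:
        raise KeyError(f"node {node_id!r} not in matrix (missing columns {missing})")
    return NodeSubmatrix(
        node_id=node_id,
        data=matrix[cols].copy(),
        timestamps=pd.to_datetime(matrix["timestamp"]).reset_index(drop=True),
    )


def time_features(timestamps: pd.Series) -> pd.DataFrame:
    """Integer calendar features: hour of day, day of month, day of week, month."""
    ts = pd.to_datetime(timestamps)
    return pd.DataFrame(
        {
            "hour": ts.dt.hour.to_numpy(),
            "day_of_month": ts.dt.day.to_numpy(),
            "day_of_week": ts.dt.dayofweek.to_numpy(),
            "month": ts.dt.month.to_numpy(),
        }
    )


def make_supervised(
    sub: NodeSubmatrix,
    target_variable: str | None = None,
    k: int = 1,
    add_time_features: bool = True,
) -> SupervisedFrame:
    """Build a k-step-ahead forecasting frame from a node submatrix.

    The target is ``target_variable`` (default: the submatrix's first column,
    temperature for raw data) shifted ``k`` steps into the future; the last
    ``k`` rows are dropped so features and target align.
    """
    if k < 1:
        raise ValueError(f"forecast horizon k must be >= 1, got {k}")
    m = len(sub.data)
    if m <= k:
        raise ValueError(f"need more than k={k} rows, got {m}")
    target = target_variable or sub.data.columns[0]
    if target not in sub.data.columns:
        raise KeyError(f"target {target!r} not among node columns {list(sub.data.columns)}")

    X = sub.data.iloc[:-k].reset_index(drop=True)
    if add_time_features:
        X = pd.concat([X, time_features(sub.timestamps.iloc[:-k])], axis=1)
    y = sub.data[target].iloc[k:].reset_index(drop=True)
    y.name = f"{target}+{k}"
    return SupervisedFrame(X=X, y=y, k=k, target_name=target)


def assemble_nodes(
    matrix: pd.DataFrame, node_ids: list[str], variable_set: str = "raw"
) -> pd.DataFrame:
    """Concatenate several nodes' variable columns (matrix column order)."""
    cols: list[str] = []
    for n in node_ids:
        cols.extend(node_columns(n, variable_set))
    return matrix[cols].copy()
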