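"""Missing-value treatment, 0-1 scaling, and leakage-free chronological splits.

The forecasting evaluation is time-ordered throughout: the train/validation
split never shuffles rows, and min-max scaling parameters are fitted on the
training portion only so that no information from the validation period leaks
into model fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import floor

import numpy as np
import pandas as pd

#: Columns with more than this fraction missing are rejected rather than
#: filled; the method was validated on records with <1 % missingness.
MAX_FILLABLE_FRACTION = 0.05


@dataclass(frozen=True)
class SplitSpec:
    """Chronological train/validation split: first floor(f*m) rows train."""

    train_fraction: float = 0.70

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError(
                f"train_fraction must lie in (0, 1), got {self.train_fraction}"
            )

    def boundary(self, n_rows: int) -> int:
        return floor(self.train_fraction * n_rows)


def fill_missing(column: pd.Series, name: str | None = None) -> pd.Series:
    """Impute gaps in one sensor column: forward fill, then backward fill.

    Backward filling only acts on a leading gap (no earlier observation to
    carry forward). Observed values are never altered.  An all-missing column
    is rejected, naming the offending node.
    """
    label = name or str(column.name)
    if column.isna().all():
        raise ValueError(f"column {label!r} has no observed values; cannot fill")
    return column.ffill().bfill()


def fill_missing_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Fill every data column of a series matrix; timestamp passes through.

    Columns missing more than ``MAX_FILLABLE_FRACTION`` of entries are
    rejected: imputation at that scale would fabricate structure.
    """
    out = matrix.copy()
    for c in matrix.columns:
        if c == "timestamp":
            continue
        frac = out[c].isna().mean()
        if frac > MAX_FILLABLE_FRACTION:
            raise ValueError(
                f"column {c!r} is {100 * frac:.1f}% missing, above the "
                f"{100 * MAX_FILLABLE_FRACTION:.0f}% fillable limit"
            )
        out[c] = fill_missing(out[c], name=c)
    return out


def scale_minmax(
    train: np.ndarray | pd.Series,
    apply_to: np.ndarray | pd.Series | None = None,
) -> tuple[np.ndarray, np.ndarray | None, tuple[float, float]]:
    """Min-max scale to [0, 1] with parameters fitted on the training data only.

    Returns ``(scaled_train, scaled_apply, (min, max))``.  Values outside the
    training range (in ``apply_to``) map outside [0, 1]; a constant training
    column scales to all zeros with a warning.
    """
    train = np.asarray(train, dtype=float)
    lo, hi = float(np.min(train)), float(np.max(train))
    if hi == lo:
        warnings.warn(
            "constant training column; min-max scaling maps it to all zeros",
            stacklevel=2,
        )
        scale = lambda x: np.zeros_like(np.asarray(x, dtype=float))
    else:
        scale = lambda x: (np.asarray(x, dtype=float) - lo) / (hi - lo)
    scaled_apply = None if apply_to is None else scale(apply_to)
    return scale(train), scaled_apply, (lo, hi)


def chronological_split(
    matrix: pd.DataFrame, spec: SplitSpec = SplitSpec()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a time-ordered matrix into leading train and trailing validation rows.

    No shuffling: the partitions are contiguous, disjoint and exhaustive, and
    every training timestamp precedes every validation timestamp.
    """
    if "timestamp" in matrix.columns:
        ts = pd.to_datetime(matrix["timestamp"])
        if not ts.is_monotonic_increasing:
            raise ValueError("rows must be sorted by timestamp before splitting")
    m = len(matrix)
    b = spec.boundary(m)
    if b == 0 or b == m:
        raise ValueError(
            f"split of {m} rows at fraction {spec.train_fraction} leaves an "
            "empty partition"
        )
    return matrix.iloc[:b].copy(), matrix.iloc[b:].copy()
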