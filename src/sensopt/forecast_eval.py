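"""Gradient-boosted one-step-ahead forecasting and RMSE scoring.

The surrogate forecaster is a stage-wise additive ensemble of regression
trees: each stage fits a tree to the negative gradient of the squared-error
loss of the current model and is added scaled by the learning rate.  Fitting
is delegated to scikit-learn's :class:`~sklearn.ensemble.GradientBoostingRegressor`,
which implements exactly this contract; determinism is guaranteed by a fixed
seed and the absence of row/column subsampling.

All model evaluation is chronological: the frame is split into a leading
training block and a trailing validation block, features (and target) are
min-max scaled with parameters fitted on the training block only, and the
validation RMSE drives every downstream selection decision.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor

from .node_model import SupervisedFrame
from .preprocess import SplitSpec, scale_minmax


@dataclass(frozen=True)
class BoostParams:
    """Hyper-parameters of the boosted-tree forecaster.

    Defaults follow the tuned operating point for greenhouse T/RH streams:
    1000 estimators at learning rate 0.01, with tree depth searched over 2-7.
    """

    n_estimators: int = 1000
    learning_rate: float = 0.01
    max_depth: int = 3
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if not (0.0 < self.learning_rate <= 1.0):
            raise ValueError("learning_rate must lie in (0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


#: Default hyper-parameter search space: depth 2-7 as the primary axis.
DEFAULT_SEARCH_SPACE: dict[str, list] = {
    "n_estimators": [100, 500, 1000],
    "learning_rate": [0.01, 0.1],
    "max_depth": [2, 3, 4, 5, 6, 7],
}


@dataclass
class FitResult:
    """A fitted forecaster with its chronological train/validation RMSEs.

    RMSEs are in the units the model was fitted in: scaled [0, 1] units by
    default (``scale=True``), raw target units otherwise.
    """

    model: GradientBoostingRegressor
    params: BoostParams
    train_rmse: float
    val_rmse: float


def rmse(actual, predicted) -> float:
    """Root mean squared error between two equal-length series."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {p.shape}")
    if a.size == 0:
        raise ValueError("rmse of empty series is undefined")
    return float(np.sqrt(np.mean((a - p) ** 2)))


def _scaled_split(
    frame: SupervisedFrame, split: SplitSpec, scale: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    m = len(frame.y)
    b = split.boundary(m)
    if b == 0 or b == m:
        raise ValueError(f"frame of {m} rows leaves an empty partition at "
                         f"fraction {split.train_fraction}")
    X = frame.X.to_numpy(dtype=float)
    y = frame.y.to_numpy(dtype=float)
    X_tr, X_va = X[:b], X[b:]
    y_tr, y_va = y[:b], y[b:]
    if scale:
        cols_tr, cols_va = [], []
        for j in range(X.shape[1]):
            lo, hi = X_tr[:, j].min(), X_tr[:, j].max()
            if hi == lo:
                cols_tr.append(np.zeros(b))
                cols_va.append(np.zeros(m - b))
            else:
                cols_tr.append((X_tr[:, j] - lo) / (hi - lo))
                cols_va.append((X_va[:, j] - lo) / (hi - lo))
        X_tr = np.column_stack(cols_tr)
        X_va = np.column_stack(cols_va)
        lo, hi = y_tr.min(), y_tr.max()
        if hi > lo:
            y_tr = (y_tr - lo) / (hi - lo)
            y_va = (y_va - lo) / (hi - lo)
        else:
            y_tr = np.zeros(b)
            y_va = np.zeros(m - b)
    return X_tr, X_va, y_tr, y_va


def fit_boosted(
    frame: SupervisedFrame,
    params: BoostParams = BoostParams(),
    split: SplitSpec = SplitSpec(),
    scale: bool = True,
) -> FitResult:
    """Fit the boosted forecaster on a supervised frame and score it.

    The frame is split chronologically (no shuffling), min-max scaled on the
    training block when ``scale`` is True, fitted, and scored by RMSE on both
    blocks.  Bit-identical predictions for identical seed and data.
    """
    if len(frame.y) == 0:
        raise ValueError("cannot fit on an empty frame")
    X_tr, X_va, y_tr, y_va = _scaled_split(frame, split, scale)
    model = GradientBoostingRegressor(
        loss="squared_error",
        n_estimators=params.n_estimators,
        learning_rate=params.learning_rate,
        max_depth=params.max_depth,
        random_state=params.rng_seed,
    )
    model.fit(X_tr, y_tr)
    return FitResult(
        model=model,
        params=params,
        train_rmse=rmse(y_tr, model.predict(X_tr)),
        val_rmse=rmse(y_va, model.predict(X_va)),
    )


def _combinations(search_space: dict[str, list]) -> list[dict]:
    keys = list(search_space)
    return [dict(zip(keys, vals)) for vals in itertools.product(*search_space.values())]


def tune(
    frame: SupervisedFrame,
    search_space: dict[str, list] | None = None,
    strategy: str = "grid",
    n_iter: int = 10,
    rng_seed: int = 0,
    base_params: BoostParams = BoostParams(),
    split: SplitSpec = SplitSpec(),
) -> BoostParams:
    """Select hyper-parameters minimizing validation RMSE.

    ``strategy="grid"`` evaluates the full cartesian product of the search
    space; ``"random"`` draws ``n_iter`` distinct combinations from it with a
    seeded generator.  Ties are broken toward the cheaper model: fewest
    estimators, then shallowest depth.
    """
    space = search_space if search_space is not None else DEFAULT_SEARCH_SPACE
    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("search space must be non-empty")
    combos = _combinations(space)
    if strategy == "random":
        rng = np.random.default_rng(rng_seed)
        take = min(n_iter, len(combos))
        idx = rng.choice(len(combos), size=take, replace=False)
        combos = [combos[i] for i in sorted(idx)]
    elif strategy != "grid":
        raise ValueError(f"unknown strategy {strategy!r}; use 'grid' or 'random'")

    best: tuple | None = None
    best_params: BoostParams | None = None
    for combo in combos:
        params = replace(base_params, **combo)
        result = fit_boosted(frame, params, split=split)
        key = (result.val_rmse, params.n_estimators, params.max_depth)
        if best is None or key < best:
            best = key
            best_params = params
    assert best_params is not None
    return best_params
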