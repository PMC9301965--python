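"""Variability and similarity analyses of greenhouse climate series.

Coefficient of variation (CV) quantifies how strongly a period's readings
fluctuate around their mean; weighted dynamic time warping (DTW) measures the
similarity of two periods' hourly series (e.g. a planted month versus an
empty-greenhouse month) under monotone alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CVReport:
    """Coefficient of variation of one variable over one period."""

    period: str
    variable: str
    mean: float
    sd: float
    cv_percent: float  # NaN when undefined (zero mean)
    undefined: bool = False


def coefficient_of_variation(
    series, period: str = "", variable: str = ""
) -> CVReport:
    """Sample standard deviation over mean, as a percentage.

    Uses the (n-1)-denominator sample standard deviation. A zero mean makes
    the ratio undefined; the report is flagged rather than raising.
    """
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("coefficient of variation needs at least 2 observations")
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if mu == 0.0:
        return CVReport(period, variable, mu, sd, float("nan"), undefined=True)
    return CVReport(period, variable, mu, sd, 100.0 * sd / mu)


@dataclass
class DTWResult:
    """Weighted-DTW alignment of two series.

    ``cost`` is the (T_u+1) x (T_v+1) dynamic-programming table (row/column 0
    are the boundary); ``path`` lists 1-based (i, j) pairs from (1, 1) to
    (T_u, T_v), pair (i, j) matching ``u[i-1]`` with ``v[j-1]``;
    ``distance = cost[T_u, T_v]``.
    """

    cost: np.ndarray
    weights: tuple[float, float, float]
    path: list[tuple[int, int]]
    distance: float


def dtw_align(
    u,
    v,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    swap_hv: bool = False,
) -> DTWResult:
    """Weighted dynamic time warping with absolute-difference local distance.

    ``weights = (w_H, w_D, w_V)`` penalize the three step directions.  The
    recursion used here is

        g(i, j) = min( g(i, j-1) + d(u_i, v_j) * w_V,
                       g(i-1, j-1) + d(u_i, v_j) * w_D,
                       g(i-1, j) + d(u_i, v_j) * w_H )

    i.e. w_V multiplies the step from g(i, j-1) and w_H the step from
    g(i-1, j).  That pairing is the opposite of the usual horizontal/vertical
    naming; ``swap_hv=True`` swaps w_H and w_V to the conventional roles.
    With symmetric weights the two conventions coincide.  Traceback from
    (T_u, T_v) prefers the diagonal on ties.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.size == 0 or v.size == 0:
        raise ValueError("both series must be non-empty")
    w_h, w_d, w_v = (float(w) for w in weights)
    if min(w_h, w_d, w_v) < 0:
        raise ValueError("weights must be non-negative")
    if swap_hv:
        w_h, w_v = w_v, w_h

    tu, tv = u.size, v.size
    g = np.full((tu + 1, tv + 1), np.inf)
    g[0, 0] = 0.0
    d = np.abs(u[:, None] - v[None, :])
    for i in range(1, tu + 1):
        di = d[i - 1]
        gi = g[i]
        gp = g[i - 1]
        for j in range(1, tv + 1):
            local = di[j - 1]
            gi[j] = min(
                gi[j - 1] + local * w_v,
                gp[j - 1] + local * w_d,
                gp[j] + local * w_h,
            )

    # traceback, diagonal preferred on ties
    path = [(tu, tv)]
    i, j = tu, tv
    while (i, j) != (1, 1):
        if i == 1:
            j -= 1
        elif j == 1:
            i -= 1
        else:
            local = d[i - 1, j - 1]
            here = g[i, j]
            if np.isclose(g[i - 1, j - 1] + local * w_d, here):
                i, j = i - 1, j - 1
            elif np.isclose(g[i, j - 1] + local * w_v, here):
                j -= 1
            else:
                i -= 1
        path.append((i, j))
    path.reverse()
    return DTWResult(
        cost=g,
        weights=(w_h, w_d, w_v) if not swap_hv else (w_v, w_d, w_h),
        path=path,
        distance=float(g[tu, tv]),
    )


def hourly_aggregate(raw: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-minute series matrix to hourly means per column.

    Each clock hour's rows are averaged (missing entries ignored); the
    emitted ``timestamp`` is the start of the hour.  A 31-day month of
    per-minute data becomes 744 rows; a 30-day month, 720.
    """
    if "timestamp" not in raw.columns:
        raise ValueError("series matrix must have a 'timestamp' column")
    ts = pd.to_datetime(raw["timestamp"])
    grouped = raw.drop(columns="timestamp").groupby(ts.dt.floor("h"), sort=True).mean()
    grouped.index.name = "timestamp"
    return grouped.reset_index()
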