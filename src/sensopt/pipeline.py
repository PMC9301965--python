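"""End-to-end orchestration: simulate/load, preprocess, transform, select, report.

A run is described by a :class:`RunConfig`; :func:`run_pipeline` executes the
full placement analysis for each requested analysis window and variable set,
writing ranking tables (CSV), a JSON summary with the optimal counts and knee
points, an RMSE-curve figure per analysis, and a manifest sufficient to
reproduce the run bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from ._version import __version__
from .forecast_eval import BoostParams
from .grid import SensorGrid
from .preprocess import SplitSpec, fill_missing_matrix
from .psychro import transform_matrix
from .selection import SelectionResult, greedy_stack, optimal_count, pareto_knees
from .synthetic import SimulationConfig, generate, read_csv

logger = logging.getLogger("sensopt")

#: Windows with fewer rows than this are skipped: too short to fit and
#: validate a forecaster meaningfully.
MIN_WINDOW_ROWS = 100

RAW_SETS = ("raw", "RH")
PSYCHRO_SETS = ("Td", "w", "h", "v")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``input_csv`` (a series-matrix CSV) or ``simulation`` (synthetic
    generator settings) provides the data.  ``window`` groups the record into
    daily, weekly or monthly analysis windows; each window is analysed
    independently for every entry of ``variable_sets``.
    """

    input_csv: str | None = None
    simulation: SimulationConfig | None = None
    grid: SensorGrid = field(default_factory=SensorGrid)
    window: str = "monthly"  # daily | weekly | monthly
    variable_sets: list[str] = field(default_factory=lambda: ["raw"])
    train_fraction: float = 0.70
    boost: BoostParams = field(default_factory=BoostParams)
    max_nodes: int | None = None
    knee_threshold: float = 10.0
    output_dir: str = "sensopt_run"
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.window not in ("daily", "weekly", "monthly"):
            raise ValueError(f"window must be daily/weekly/monthly, got {self.window!r}")
        if not self.variable_sets:
            raise ValueError("at least one variable set is required")
        if self.input_csv is None and self.simulation is None:
            raise ValueError("provide input_csv or a simulation config")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "boost" in d and isinstance(d["boost"], dict):
            d["boost"] = BoostParams(**d["boost"])
        if "grid" in d and isinstance(d["grid"], dict):
            g = dict(d["grid"])
            g["columns"] = tuple(g.get("columns", ()))
            g["rows"] = tuple(g.get("rows", ()))
            d["grid"] = SensorGrid(**g)
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def _windows(matrix: pd.DataFrame, window: str):
    ts = pd.to_datetime(matrix["timestamp"])
    if window == "daily":
        keys = ts.dt.strftime("%Y-%m-%d")
    elif window == "weekly":
        iso = ts.dt.isocalendar()
        keys = iso["year"].astype(str) + "-W" + iso["week"].astype(str).str.zfill(2)
    else:
        keys = ts.dt.strftime("%Y-%m")
    for label, idx in matrix.groupby(keys.to_numpy(), sort=True).groups.items():
        yield str(label), matrix.loc[idx].reset_index(drop=True)


def _nodes_in(matrix: pd.DataFrame) -> list[str]:
    return [c[:-2] for c in matrix.columns if c.endswith("_T")]


def render_ranking_table(result: SelectionResult) -> tuple[pd.DataFrame, str]:
    """Ranking table with the optimal row flagged (CSV frame + text rendering).

    Row indices are 0-based, so the optimal flag sits at index
    ``optimal_count - 1``.
    """
    table = result.to_frame()
    if table.empty:
        raise ValueError("empty selection result")
    opt = optimal_count(result)
    table["optimal"] = ["*" if i == opt - 1 else "" for i in table["index"]]
    lines = [f"{'Index':>5}  {'RMSE':>10}  Opt  Sensor location(s)"]
    for _, row in table.iterrows():
        lines.append(
            f"{row['index']:>5}  {row['rmse']:>10.7f}  {row['optimal'] or ' ':>3}  "
            f"{row['sensor_locations']}"
        )
    return table, "\n".join(lines)


def plot_rmse_curve(result: SelectionResult, path: Path) -> None:
    """Save the cumulative RMSE curve (sensor count vs validation RMSE)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = range(1, len(result.cumulative_rmse) + 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(counts, result.cumulative_rmse, marker="o")
    opt = optimal_count(result)
    ax.axvline(opt, color="crimson", linestyle="--", label=f"optimal = {opt}")
    ax.set_xlabel("number of sensors")
    ax.set_ylabel(f"validation RMSE ({result.variable_set})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full placement analysis; returns the run report dict.

    For every analysis window and variable set: fill missing values, derive
    psychrometric properties where needed, run greedy selection, and write
    the ranking table, summary JSON and (optionally) the RMSE-curve figure.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.input_csv is not None:
        matrix = read_csv(config.input_csv)
        source = {"input_csv": str(config.input_csv)}
    else:
        assert config.simulation is not None
        matrix = generate(config.grid, config.simulation)
        source = {"simulation": config.simulation.to_dict()}

    nodes = _nodes_in(matrix)
    split = SplitSpec(config.train_fraction)
    report: dict = {
        "sensopt_version": __version__,
        "config": config.to_dict(),
        "source": source,
        "analyses": [],
    }

    for label, window in _windows(matrix, config.window):
        if len(window) < MIN_WINDOW_ROWS:
            logger.warning("window %s has %d rows (<%d); skipped",
                           label, len(window), MIN_WINDOW_ROWS)
            continue
        filled = fill_missing_matrix(window)
        psychro = None
        for var in config.variable_sets:
            if var in PSYCHRO_SETS:
                if psychro is None:
                    psychro = transform_matrix(filled)
                data = psychro
            else:
                data = filled
            result = greedy_stack(
                data, nodes, variable_set=var, params=config.boost,
                split=split, max_nodes=config.max_nodes,
            )
            table, text = render_ranking_table(result)
            stem = f"ranking_{label}_{var}"
            table.to_csv(out_dir / f"{stem}.csv", index=False)
            try:
                knees = pareto_knees(result, config.knee_threshold)
            except ValueError:
                knees = []
            if config.make_plots:
                plot_rmse_curve(result, out_dir / f"{stem}.png")
            report["analyses"].append(
                {
                    "window": label,
                    "variable_set": var,
                    "ranked_nodes": result.ranked_nodes,
                    "cumulative_rmse": result.cumulative_rmse,
                    "optimal_count": optimal_count(result),
                    "knee_points": [
                        {"index": i, "reduction_pct": r} for i, r in knees
                    ],
                    "table_text": text,
                }
            )

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(
            {"sensopt_version": __version__, "config": config.to_dict()},
            fh,
            indent=2,
        )
    return report
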