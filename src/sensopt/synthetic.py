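"""Synthetic greenhouse microclimate generator.

Emulates the statistical structure of per-minute temperature/relative-humidity
records from a grid of 2-in-1 sensor nodes inside a protected cultivation
system: a seasonal linear trend, a diurnal sinusoid, a spatially correlated
random field over the node coordinates (exponential kernel, AR(1) in time),
independent per-sensor noise, a small fraction of missing-completely-at-random
entries, and an optional "plants present" perturbation that inflates humidity
variability.  A subset of nodes can be planted as *informative*: they track
the latent field with reduced sensor noise, providing ground truth for
ranking-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .grid import SensorGrid

MINUTES_PER_DAY = 1440


@dataclass
class SimulationConfig:
    """Parameters of the synthetic microclimate simulation.

    Attributes
    ----------
    n_days : int
        Length of the simulated window in days.
    sampling_interval : int
        Minutes between consecutive samples (>= 1; default 1, per-minute).
    base_mean_temp : float
        Long-run mean dry-bulb temperature, degC.
    base_diurnal_amplitude : float
        Half peak-to-trough amplitude of the diurnal temperature cycle, degC.
    seasonal_trend : float
        Linear drift of the daily mean temperature, degC per day.
    spatial_correlation_length : float
        e-folding length of the exponential spatial kernel, metres.
    field_sd : float
        Standard deviation of the spatially correlated latent field, degC.
    temporal_corr_minutes : float
        e-folding time of the latent field's AR(1) dynamics, minutes.
    sensor_noise_sd_temp, sensor_noise_sd_rh : float
        Independent per-reading sensor noise, degC and %RH. Defaults match
        sensor specs of +/-0.3 degC and +/-2 %RH.
    base_mean_rh : float
        Long-run mean relative humidity, %.
    humidity_coupling : float
        %RH decrease per degC of temperature anomaly (humidity moves
        opposite to temperature).
    informative_nodes : list of str
        Planted ground-truth nodes for ranking-recovery experiments.  Each
        sits at the centre of an independent microclimate disturbance source
        (think heater, vent or fan plume) whose signal spreads to the rest of
        the house one sampling step later, attenuated over
        ``spatial_correlation_length``; the node also samples the field with
        sensor noise scaled by ``informative_noise_factor``.  A sensor at a
        source thus leads every other location by one step, making the
        planted set the genuinely most informative subset for one-step-ahead
        forecasting.
    informative_noise_factor : float
        Noise multiplier for informative nodes (< 1).
    source_sd : float
        Standard deviation of each planted disturbance source at its centre,
        degC.
    source_corr_minutes : float
        e-folding time of the disturbance sources' AR(1) dynamics, minutes.
    noise_drift : float
        Linear growth of sensor noise over the window (0 = stable sensors;
        1 = noise sd doubles by the end), emulating degradation of the
        ordinary sensors.  Informative nodes are premium calibrated sensors
        and do not drift.
    missing_fraction : float
        Expected fraction of data cells set missing, in [0, 0.05).
    plants_present : bool
        When True the canopy transpires: mean humidity rises by ~8 %RH,
        humidity noise is inflated 1.5x, and evaporative cooling damps the
        diurnal temperature swing by 15 %.
    rng_seed : int
        Seed for all randomness; identical seed+config gives identical output.
    start : str
        ISO date of the first sample.
    """

    n_days: int = 31
    sampling_interval: int = 1
    base_mean_temp: float = 18.0
    base_diurnal_amplitude: float = 6.0
    seasonal_trend: float = 0.05
    spatial_correlation_length: float = 6.0
    field_sd: float = 1.5
    temporal_corr_minutes: float = 120.0
    sensor_noise_sd_temp: float = 0.3
    sensor_noise_sd_rh: float = 2.0
    base_mean_rh: float = 70.0
    humidity_coupling: float = 2.5
    informative_nodes: list[str] = field(default_factory=list)
    informative_noise_factor: float = 0.2
    noise_drift: float = 0.0
    source_sd: float = 3.5
    source_corr_minutes: float = 30.0
    source_coupling: float = 0.25
    missing_fraction: float = 0.005
    plants_present: bool = False
    rng_seed: int = 0
    start: str = "2022-03-01"

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError(f"n_days must be >= 1, got {self.n_days}")
        if self.sampling_interval < 1:
            raise ValueError(
                f"sampling_interval must be >= 1 minute, got {self.sampling_interval}"
            )
        if not (0.0 <= self.missing_fraction < 0.05):
            raise ValueError(
                f"missing_fraction must lie in [0, 0.05), got {self.missing_fraction}"
            )
        if self.informative_noise_factor <= 0:
            raise ValueError("informative_noise_factor must be positive")
        if self.field_sd < 0 or self.sensor_noise_sd_temp < 0 or self.sensor_noise_sd_rh < 0:
            raise ValueError("standard deviations must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def _spatial_chol(grid: SensorGrid, length: float) -> np.ndarray:
    """Cholesky factor of the exponential-kernel covariance over node coords."""
    coords = np.array([grid.coordinates()[n] for n in grid.nodes])
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    k = np.exp(-d / length)
    # jitter keeps the factorization stable for coincident/near nodes
    return np.linalg.cholesky(k + 1e-9 * np.eye(len(k)))


def _ar1_field(
    rng: np.random.Generator,
    chol: np.ndarray,
    n_steps: int,
    rho: float,
    sd: float,
) -> np.ndarray:
    """Spatially correlated field with AR(1) dynamics, shape (n_nodes, n_steps).

    Stationary: each node's marginal sd equals ``sd`` at every step.
    """
    n_nodes = chol.shape[0]
    z = chol @ rng.standard_normal((n_nodes, n_steps))
    x0 = chol @ rng.standard_normal(n_nodes)
    innov = np.sqrt(1.0 - rho**2) * z
    innov[:, 0] = 0.0
    x = lfilter([1.0], [1.0, -rho], innov, axis=1)
    # add the decaying contribution of the stationary start value
    x += x0[:, None] * rho ** np.arange(n_steps)[None, :]
    return sd * x


def _coupled_sources(
    rng: np.random.Generator, config: SimulationConfig, n_steps: int
) -> np.ndarray:
    """Disturbance-source signals, shape (n_sources, n_steps).

    Source 1 is the *master* (mixing-chamber) signal: an AR(1) driven, with
    weight ``source_coupling``, by the current states of the remaining
    sources, which are independent AR(1) unit signals of sd ``source_sd``.
    All relax at the rate implied by ``source_corr_minutes``.  The master's
    next state thus depends on the units' present states, so sensors reading
    the unit signals carry one-step-ahead information about the master that
    the master's own sensor cannot provide.
    """
    k = len(config.informative_nodes)
    a = float(np.exp(-config.sampling_interval / config.source_corr_minutes))
    s = config.source_sd
    innov_sd = s * np.sqrt(1.0 - a * a)
    F = np.empty((k, n_steps))
    F[:, 0] = s * rng.standard_normal(k)
    eps = rng.standard_normal((k, n_steps))
    if k > 1:
        c = config.source_coupling / np.sqrt(k - 1)
        for t in range(1, n_steps):
            F[1:, t] = a * F[1:, t - 1] + innov_sd * eps[1:, t]
            F[0, t] = (
                a * F[0, t - 1]
                + c * F[1:, t - 1].sum()
                + 0.2 * s * eps[0, t]
            )
    else:
        for t in range(1, n_steps):
            F[0, t] = a * F[0, t - 1] + innov_sd * eps[0, t]
    return F


def generate(grid: SensorGrid, config: SimulationConfig) -> pd.DataFrame:
    """Simulate a timestamped temperature/humidity matrix for every grid node.

    Returns a DataFrame with one ``timestamp`` column plus two columns per
    node (``"<node>_T"`` in degC, ``"<node>_RH"`` in %), and
    ``n_days * 1440 / sampling_interval`` rows.  Missing entries are injected
    as NaN at rate ``config.missing_fraction``.  Output is a deterministic
    function of (grid, config).
    """
    unknown = set(config.informative_nodes) - set(grid.nodes)
    if unknown:
        raise ValueError(f"informative_nodes not in grid: {sorted(unknown)}")

    rng = np.random.default_rng(config.rng_seed)
    nodes = grid.nodes
    n_nodes = len(nodes)
    n_steps = config.n_days * MINUTES_PER_DAY // config.sampling_interval

    t_minutes = np.arange(n_steps) * config.sampling_interval
    t_days = t_minutes / MINUTES_PER_DAY
    hour = (t_minutes % MINUTES_PER_DAY) / 60.0

    # shared deterministic structure: seasonal drift + diurnal cycle (peak
    # 14:00); a transpiring canopy damps the diurnal swing
    amplitude = config.base_diurnal_amplitude * (0.85 if config.plants_present else 1.0)
    seasonal = config.base_mean_temp + config.seasonal_trend * t_days
    diurnal = amplitude * np.cos(2 * np.pi * (hour - 14.0) / 24.0)

    chol = _spatial_chol(grid, config.spatial_correlation_length)
    rho = float(np.exp(-config.sampling_interval / config.temporal_corr_minutes))
    latent = _ar1_field(rng, chol, n_steps, rho, config.field_sd)

    # static spatial offsets (e.g. proximity to heating pipes / vents)
    offsets = 0.8 * (chol @ rng.standard_normal(n_nodes))

    temp_latent = seasonal[None, :] + diurnal[None, :] + latent + offsets[:, None]

    # planted disturbance sources (informative nodes): the first planted node
    # sits at the mixing chamber of the air-conditioning loop and reads the
    # master signal; the other planted nodes sit at conditioning units whose
    # localized plumes only their own sensors see, but whose present states
    # drive the master's next state.  The planted sensors therefore jointly
    # lead the master for one-step-ahead forecasting, while every other
    # location reads only the shared canopy field.
    if config.informative_nodes and config.source_sd > 0:
        F = _coupled_sources(rng, config, n_steps)
        for ki, src in enumerate(config.informative_nodes):
            temp_latent[nodes.index(src)] += F[ki]

    noise_scale = np.ones(n_nodes)
    informative = set(config.informative_nodes)
    for i, n in enumerate(nodes):
        if n in informative:
            noise_scale[i] = config.informative_noise_factor

    ramp = np.arange(n_steps) / max(n_steps - 1, 1)
    drifts = np.ones(n_nodes)[:, None] + (
        config.noise_drift
        * np.array([0.0 if n in informative else 1.0 for n in nodes])[:, None]
        * ramp[None, :]
    )
    temp = temp_latent + (
        config.sensor_noise_sd_temp * noise_scale[:, None] * drifts
        * rng.standard_normal((n_nodes, n_steps))
    )

    plants_factor = 1.5 if config.plants_present else 1.0
    rh_base = config.base_mean_rh + (8.0 if config.plants_present else 0.0)
    rh_latent = (
        rh_base - config.humidity_coupling * (temp_latent - config.base_mean_temp)
    )
    rh = rh_latent + (
        plants_factor * config.sensor_noise_sd_rh * noise_scale[:, None]
        * drifts * rng.standard_normal((n_nodes, n_steps))
    )

    temp = np.clip(temp, -20.0, 80.0)
    rh = np.clip(rh, 0.0, 100.0)

    data = np.empty((n_steps, 2 * n_nodes))
    data[:, 0::2] = temp.T
    data[:, 1::2] = rh.T

    if config.missing_fraction > 0:
        mask = rng.random(data.shape) < config.missing_fraction
        data[mask] = np.nan

    timestamps = pd.date_range(
        config.start, periods=n_steps, freq=f"{config.sampling_interval}min"
    )
    columns = []
    for n in nodes:
        columns.extend([f"{n}_T", f"{n}_RH"])
    out = pd.DataFrame(data, columns=columns)
    out.insert(0, "timestamp", timestamps)
    return out


def planted_truth(config: SimulationConfig) -> list[str]:
    """Ground-truth node ordering for ranking-recovery experiments.

    The planted informative nodes, most informative first (the order given in
    the config). Empty when no nodes were planted.
    """
    return list(config.informative_nodes)


def write_csv(matrix: pd.DataFrame, path) -> None:
    """Write a series matrix as CSV: ISO-8601 timestamps, empty fields for NaN."""
    out = matrix.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, na_rep="")


def read_csv(path) -> pd.DataFrame:
    """Read a series matrix CSV written by :func:`write_csv`."""
    df = pd.read_csv(path)
    if "timestamp" not in df.columns:
        raise ValueError("series matrix CSV must have a 'timestamp' column")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df
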