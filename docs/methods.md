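# Methods

## The placement problem and the selection procedure

A protected cultivation system is monitored by a grid of 2-in-1
temperature/relative-humidity nodes (default: 8 columns A–H spaced 3 m, 7
rows spaced 1 m, 56 nodes). The goal is a minimal subset of locations whose
readings describe the house's air–vapor state.

The selection objective is one-step-ahead forecastability. For a candidate
feature set X_t and target y_{t+k} (k = 1 sampling step), a gradient-boosted
regression-tree model G_M(x) is fitted stage-wise: each stage fits a tree to
the negative gradient of the squared-error loss of the current model and is
added scaled by the learning rate μ. The model quality is the RMSE on a
chronologically held-out validation block. Two stages:

1. *Anchor ranking.* Every node is scored by a model that forecasts the
   node's own reading from its contemporaneous variables plus integer
   calendar features (hour, day-of-month, day-of-week, month). The node
   with the lowest validation RMSE is the anchor; ties break toward grid
   order (A1 < A2 < … < H7).
2. *Greedy stacking.* The anchor's one-step-ahead reading is fixed as the
   target. Iteratively, the candidate node whose variable columns — added
   to the growing feature set — minimize the validation RMSE is appended,
   and that RMSE is recorded. The resulting cumulative curve r_1 ≥ r_2 …
   is the sensor-count/error trade-off.

The *optimal count* is the earliest global minimum of the curve. A
first-local-rise rule would truncate genuinely non-monotonic curves (the
error can dip again after a small rise), so the global minimum is used; on
exact ties the earliest index wins. *Knee points* are local maxima of the
consecutive relative reduction 100·(r_i − r_{i+1})/r_i above a configurable
threshold (default 10 %).

All model selection uses validation (never training) RMSE; scaling
parameters are fitted on the training block only. RMSEs are reported in
scaled [0, 1] target units by default (`scale=False` gives raw units).

## Psychrometrics

Derived per node from dry-bulb temperature T (°C) and RH (%) at total
pressure P (default 101 325 Pa, configurable):

- Dew point: `Td = T − (100 − RH)/5`. This linear rule is exact at
  saturation and accurate to ~1 °C for RH ≳ 50 %; a Magnus-inversion
  alternative (`method="magnus"`) covers the full range.
- Vapor pressure: `Pw = (RH/100)·Psat(T)` with Magnus form
  `Psat = 610.94·exp(17.625·T/(243.04 + T))` Pa (within 1 % of steam-table
  values across the sensor range −20…80 °C).
- Humidity ratio: `w = 0.62198·Pw/(P − Pw)` (kg water / kg dry air).
- Enthalpy: `h = 1.006·T + w·(2501 + 1.805·T)` (kJ/kg dry air).
- Specific volume: `v = R_da·(T + 273.15)/(P − Pw)` with
  R_da = 287.055 J/(kg·K). The ideal-gas relation requires absolute
  temperature, so T is converted to kelvin.

## Forecaster settings

`BoostParams` defaults to 1000 estimators at learning rate 0.01 with tree
depth searched over 2–7 (grid or seeded random search; ties prefer fewer
estimators, then shallower trees). No stochastic row/column subsampling is
used, so a fixed seed gives bit-identical refits. The bundled experiments
use a cheaper converged operating point (150 estimators, learning rate 0.3,
depth 2): at high shrinkage an underfit model can appear to improve when
irrelevant features are added merely because extra split choices accelerate
convergence, which would bias the greedy curve downward; running the
learner to convergence removes that artifact.

## Variability and similarity analyses

- Coefficient of variation: 100·σ/μ with the sample (n−1) standard
  deviation; a zero mean is flagged undefined rather than raising.
- Weighted DTW with absolute-difference local cost. The recursion weights
  the step from g(i, j−1) with w_V and the step from g(i−1, j) with w_H —
  the opposite of the usual horizontal/vertical naming; this pairing is
  implemented as stated with a documented `swap_hv` flag to exchange the
  roles. Default weights (1, 1, 1) make the two conventions coincide.
  Boundary conditions: g(0,0) = 0, first row/column ∞; traceback prefers
  the diagonal on ties. Complexity is O(T_u·T_v); month-scale hourly
  series (744×720) align in seconds.
- Hourly aggregation takes the arithmetic mean within each clock hour
  ("hourly reading" could also mean an instantaneous sample; the mean is
  robust to the small imputation fraction).

## Synthetic microclimate generator

Per-node temperature is
`seasonal trend + diurnal sinusoid (peak 14:00) + spatially correlated
field + static spatial offset + sensor noise`, with humidity
anti-correlated with temperature and clipped to [0, 100] %. The spatial
field has an exponential kernel over the physical node coordinates
(correlation length default 6 m) and AR(1) dynamics in time (default
e-folding 120 min), so nearby nodes co-vary more than distant ones and each
node's series is diurnally periodic. Missingness is
missing-completely-at-random (default 0.5 %, configurable below 5 %).
`plants_present` emulates a transpiring canopy: +8 %RH mean, 1.5× humidity
noise, 15 % damped diurnal temperature swing.

Default magnitudes (18 °C mean, 6 °C diurnal half-amplitude, 1.5 °C field
sd, 0.3 °C / 2 %RH sensor noise) follow typical temperate-greenhouse
records and the nominal ±0.3 °C / ±2 % sensor accuracy.

### Planted ground truth

For ranking-recovery experiments the generator can plant *informative
nodes*. Their construction matters: with a single shared persistent field,
the anchor's own present reading already carries nearly all recoverable
information about its future, peer sensors are almost redundant for a tree
ensemble, and no subset is identifiably "best". The planted design
therefore gives the informative nodes structurally complementary signals,
with a physical reading of a ducted air-conditioning loop:

- The first planted node sits at the loop's *mixing chamber* and reads the
  master signal F₁ instantly.
- Each remaining planted node sits at a *conditioning unit* whose localized
  plume only its own sensor sees; the units' present states drive the
  master's next state: `F₁(t+1) = a·F₁(t) + c·Σ_k F_k(t) + ε`.
- Ordinary canopy nodes read only the shared canopy field, with larger
  sensor noise (`informative_noise_factor`, default 0.2 → a 5× noise
  ratio) and, optionally, noise that drifts upward over the record
  (`noise_drift`), emulating uncalibrated sensors degrading.

Under this construction the mixing-chamber sensor is the most predictable
location (it wins the anchor step), each unit sensor carries one-step-ahead
information about the anchor that no other node has (they win the greedy
steps), and ordinary nodes add nothing — so the planted ordering is the
objectively correct answer the selection should recover.

## Validation experiments and problem sizes

- *Planted recovery* (`sensopt.experiments`): 4×4 grid (16 nodes), 3
  planted, 30 days at 30-minute sampling (1440 rows), noise 4.5 °C/8 %RH
  with 5× informative ratio and noise drift 2 (ordinary sensors' noise
  triples), forecaster at the converged operating point, greedy run to 6
  nodes. Across 20 seeds the planted trio tops the ranking and the optimal
  count stays ≤ 5 in ≥ 90 % of runs. These sizes keep a full 20-seed study
  within minutes on one CPU while leaving clear planted/ordinary
  separation.
- *Greedy-step optimality*: an 8-node instance; every greedy addition is
  re-verified by independently refitting all rejected candidates.
- *DTW oracle*: exhaustive path enumeration over all series pairs with
  lengths ≤ 3 over a 3-symbol alphabet (1521 ordered pairs), plus 300
  seeded random pairs with lengths 4–6; enumerating all ~1.2 M pairs up to
  length 6 adds no coverage per unit cost, so the longer lengths are
  sampled.
- *Formula oracles*: 1000 random (T, RH) pairs against independent
  step-by-step evaluations, agreement ≤ 10⁻⁹ relative.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the method relies on —
diurnal periodicity, spatial coherence, sensor noise, sparse missingness,
and a known most-informative subset — so passing tests demonstrate that the
pipeline's mechanics (preprocessing, psychrometrics, model fitting, greedy
search, stopping rule) are correct and that the method recovers planted
structure when it exists. It does not emulate ventilation-driven airflow
fields, radiation load, actuator feedback, or rare sensor faults, so
recovery rates here say nothing about which locations are optimal in any
particular real greenhouse; on real data the selected sets are expected to
vary with season, as the windowed (daily/weekly/monthly) pipeline makes
visible.

## Numerical choices and degenerate inputs

- Split boundary: `floor(train_fraction·m)`; splits leaving an empty
  partition are rejected.
- Constant training columns min–max scale to all zeros with a warning.
- Columns more than 5 % missing are rejected rather than imputed; an
  all-missing column is an error naming the node.
- Selection ties (identical RMSEs) resolve to the earliest node in grid
  order; tuning ties resolve to the cheaper model.
- The spatial covariance gets a 10⁻⁹ jitter before Cholesky
  factorization.
- The 70/30 split is applied per analysis window (per month/week/day), not
  over a multi-month record.

## Known limitations

- The greedy curve's tail is estimated by taking a minimum over many
  near-equivalent candidates each step, which biases flat tails slightly
  downward; the optimal count can therefore land one or two positions past
  the true plateau start on noisy records.
- Eq-style dew point (linear rule) degrades below ~50 %RH; switch to the
  Magnus inversion for dry climates.
- Hyper-parameters are tuned once and held fixed across greedy iterations
  (a `tune` call per iteration is possible but costly); re-tuning per step
  could change late-ranking order.
- DTW here is unconstrained (no Sakoe–Chiba band) and univariate.
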