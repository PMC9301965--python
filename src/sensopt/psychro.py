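"""Psychrometric properties of moist air from dry-bulb temperature and RH.

Four derived quantities describe the greenhouse air-vapor mixture better than
the raw sensor readings: dew point temperature Td (degC), humidity ratio w
(kg water vapor / kg dry air), specific enthalpy h (kJ/kg dry air), and
specific volume v (m^3/kg dry air).

Two formulations of the dew point are provided.  The default is the simple
linear rule ``Td = T - (100 - RH)/5``, accurate to about 1 degC for
RH >~ 50 %; ``method="magnus"`` switches to inverting the Magnus saturation
curve, valid over the full RH range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Gas constant for dry air, J/(kg K).
R_DA = 287.055

#: Standard atmospheric pressure, Pa.
P_ATM = 101325.0

#: Ratio of molecular weights of water vapor and dry air.
EPSILON = 0.62198

# Magnus coefficients (Alduchov & Eskridge fit, water surface)
_MAGNUS_A = 610.94
_MAGNUS_B = 17.625
_MAGNUS_C = 243.04


def _check_rh(RH) -> np.ndarray:
    RH = np.asarray(RH, dtype=float)
    if np.any((RH < 0) | (RH > 100)):
        raise ValueError("relative humidity must lie in [0, 100] %")
    return RH


def dew_point(T, RH, method: str = "linear"):
    """Dew point temperature, degC.

    ``method="linear"``: Td = T - (100 - RH)/5, the simple approximation
    (exact at saturation, where Td = T).  ``method="magnus"``: inverts the
    Magnus formula; requires RH > 0.
    """
    T = np.asarray(T, dtype=float)
    RH = _check_rh(RH)
    if method == "linear":
        td = T - (100.0 - RH) / 5.0
    elif method == "magnus":
        if np.any(RH <= 0):
            raise ValueError("Magnus dew point undefined at RH = 0")
        gamma = np.log(RH / 100.0) + _MAGNUS_B * T / (_MAGNUS_C + T)
        td = _MAGNUS_C * gamma / (_MAGNUS_B - gamma)
    else:
        raise ValueError(f"unknown dew point method: {method!r}")
    return td if td.ndim else float(td)


def saturation_vapor_pressure(T):
    """Saturation vapor pressure over water, Pa (Magnus form).

    Accurate to well under 1 % over the sensor range [-20, 80] degC;
    strictly increasing in T.
    """
    T = np.asarray(T, dtype=float)
    p = _MAGNUS_A * np.exp(_MAGNUS_B * T / (_MAGNUS_C + T))
    return p if p.ndim else float(p)


def vapor_pressure(T, RH, P: float = P_ATM):
    """Partial pressure of water vapor, Pa: Pw = (RH/100) * Psat(T)."""
    RH = _check_rh(RH)
    pw = (RH / 100.0) * saturation_vapor_pressure(T)
    return pw if np.ndim(pw) else float(pw)


def humidity_ratio(Pw, P: float = P_ATM):
    """Humidity ratio w = 0.62198 Pw / (P - Pw), kg water per kg dry air."""
    Pw = np.asarray(Pw, dtype=float)
    if np.any(Pw < 0):
        raise ValueError("vapor pressure must be non-negative")
    if np.any(Pw >= P):
        raise ValueError("vapor pressure must be below total pressure")
    w = EPSILON * Pw / (P - Pw)
    return w if w.ndim else float(w)


def enthalpy(T, w):
    """Specific enthalpy of moist air, kJ/kg dry air: 1.006 T + w (2501 + 1.805 T)."""
    T = np.asarray(T, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("humidity ratio must be non-negative")
    h = 1.006 * T + w * (2501.0 + 1.805 * T)
    return h if h.ndim else float(h)


def specific_volume(T, Pw, P: float = P_ATM):
    """Specific volume of moist air per kg dry air, m^3/kg.

    Ideal-gas relation v = R_da T_abs / (P - Pw) with T_abs in kelvin.
    """
    T = np.asarray(T, dtype=float)
    Pw = np.asarray(Pw, dtype=float)
    if np.any(Pw >= P):
        raise ValueError("vapor pressure must be below total pressure")
    v = R_DA * (T + 273.15) / (P - Pw)
    return v if v.ndim else float(v)


#: Column suffixes of the derived properties, in emission order.
PROPERTY_SUFFIXES = ("Td", "w", "h", "v")


def transform_matrix(
    raw: pd.DataFrame,
    P: float = P_ATM,
    dew_point_method: str = "linear",
) -> pd.DataFrame:
    """Derive the four psychrometric properties for every node in a matrix.

    ``raw`` is a series matrix with a ``timestamp`` column and ``<node>_T`` /
    ``<node>_RH`` pairs, already free of missing values.  Returns a matrix
    with the same timestamps and four columns per node, suffixed
    ``_Td``, ``_w``, ``_h``, ``_v``.
    """
    if "timestamp" not in raw.columns:
        raise ValueError("input must have a 'timestamp' column")
    data_cols = [c for c in raw.columns if c != "timestamp"]
    if raw[data_cols].isna().any().any():
        raise ValueError(
            "input contains missing values; run preprocessing (fill_missing) first"
        )
    nodes = [c[:-2] for c in data_cols if c.endswith("_T")]
    out = {"timestamp": raw["timestamp"].to_numpy()}
    for n in nodes:
        rh_col = f"{n}_RH"
        if rh_col not in raw.columns:
            raise ValueError(f"node {n} has a temperature column but no {rh_col}")
        T = raw[f"{n}_T"].to_numpy(dtype=float)
        RH = raw[rh_col].to_numpy(dtype=float)
        pw = vapor_pressure(T, RH, P)
        w = humidity_ratio(pw, P)
        out[f"{n}_Td"] = dew_point(T, RH, method=dew_point_method)
        out[f"{n}_w"] = w
        out[f"{n}_h"] = enthalpy(T, w)
        out[f"{n}_v"] = specific_volume(T, pw, P)
    return pd.DataFrame(out)
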