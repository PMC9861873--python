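"""Henriques damage integral and burn-time extraction.

Thermal damage accumulates as a first-order Arrhenius process,
Omega = integral of P * exp(-dE/(R T)) dt, evaluated at the
epidermis-dermis and dermis-subcutaneous interfaces.  Accumulation starts
only once an interface exceeds the 44 degC onset; the kinetic constants
switch bands at 50 degC (the boundary belongs to the lower band).
Omega = 1 at the epidermis-dermis interface marks a 2nd degree burn, at the
dermis-subcutaneous interface a 3rd degree burn; 1st degree uses
Omega >= 0.53 at the epidermis-dermis interface (Torvi-lineage convention,
configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ONSET_K",
    "BAND_SPLIT_K",
    "InterfaceKinetics",
    "BurnModelParams",
    "BurnState",
    "omega_increment",
    "omega_rate",
    "accumulate",
    "accumulate_series",
    "burn_times",
    "first_crossing",
]

ONSET_K = 44.0 + 273.15        # damage onset, K
BAND_SPLIT_K = 50.0 + 273.15   # kinetic band boundary, K


@dataclass
class InterfaceKinetics:
    """(P, dE/R) pairs for the two temperature bands of one interface."""

    P_low: float       # 1/s, 44-50 degC
    dE_R_low: float    # K
    P_high: float      # 1/s, > 50 degC
    dE_R_high: float   # K

    def __post_init__(self):
        if min(self.P_low, self.dE_R_low, self.P_high, self.dE_R_high) <= 0:
            raise ValueError("kinetic constants must be positive")


@dataclass
class BurnModelParams:
    """Kinetics per interface plus the damage thresholds per burn degree."""

    epidermis_dermis: InterfaceKinetics = field(
        default_factory=lambda: InterfaceKinetics(2.185e124, 93534.9, 1.823e51, 39109.8)
    )
    dermis_subcutaneous: InterfaceKinetics = field(
        default_factory=lambda: InterfaceKinetics(4.32e64, 50000.0, 9.39e104, 80000.0)
    )
    omega_first_degree: float = 0.53   # at epidermis-dermis
    omega_second_degree: float = 1.0   # at epidermis-dermis
    omega_third_degree: float = 1.0    # at dermis-subcutaneous
    gas_constant: float = 8.31  # J/(mol K); unused (dE/R is given directly)


@dataclass
class BurnState:
    """Accumulated damage and first-crossing burn times (NaN = not reached)."""

    omega_ed: float = 0.0
    omega_ds: float = 0.0
    t: float = 0.0
    t_first: float = math.nan
    t_second: float = math.nan
    t_third: float = math.nan


def omega_rate(T, kin: InterfaceKinetics):
    """Damage rate dOmega/dt, 1/s: zero below onset, Arrhenius above,
    band-selected at 50 degC (boundary in the lower band)."""
    T = np.asarray(T, dtype=float)
    low = np.exp(np.log(kin.P_low) - kin.dE_R_low / T)
    high = np.exp(np.log(kin.P_high) - kin.dE_R_high / T)
    rate = np.where(T <= BAND_SPLIT_K, low, high)
    rate = np.where(T < ONSET_K, 0.0, rate)
    return float(rate) if rate.ndim == 0 else rate


def omega_increment(T: float, dt: float, kin: InterfaceKinetics) -> float:
    """Rectangle-rule damage increment over one step of length dt."""
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    return omega_rate(T, kin) * dt


def accumulate_series(T_series, dt: float, kin: InterfaceKinetics) -> np.ndarray:
    """Cumulative Omega(t_k) over a uniformly sampled temperature history,
    trapezoidal rule on the solver grid; Omega(t_0) = 0."""
    rate = omega_rate(np.asarray(T_series, dtype=float), kin)
    inc = 0.5 * (rate[1:] + rate[:-1]) * dt
    return np.concatenate([[0.0], np.cumsum(inc)])


def accumulate(
    burn: BurnState,
    T_ed: float,
    T_ds: float,
    dt: float,
    params: BurnModelParams,
    _prev: tuple[float, float] | None = None,
) -> BurnState:
    """Advance both interface integrals by one trapezoidal step and record
    threshold first-crossing times (linearly interpolated inside a step)."""
    r_ed = omega_rate(T_ed, params.epidermis_dermis)
    r_ds = omega_rate(T_ds, params.dermis_subcutaneous)
    if _prev is None:
        _prev = (r_ed, r_ds)
    new_ed = burn.omega_ed + 0.5 * (_prev[0] + r_ed) * dt
    new_ds = burn.omega_ds + 0.5 * (_prev[1] + r_ds) * dt
    t0, t1 = burn.t, burn.t + dt
    out = BurnState(new_ed, new_ds, t1, burn.t_first, burn.t_second, burn.t_third)
    if math.isnan(out.t_first) and new_ed >= params.omega_first_degree:
        out.t_first = _interp_crossing(t0, t1, burn.omega_ed, new_ed, params.omega_first_degree)
    if math.isnan(out.t_second) and new_ed >= params.omega_second_degree:
        out.t_second = _interp_crossing(t0, t1, burn.omega_ed, new_ed, params.omega_second_degree)
    if math.isnan(out.t_third) and new_ds >= params.omega_third_degree:
        out.t_third = _interp_crossing(t0, t1, burn.omega_ds, new_ds, params.omega_third_degree)
    return out


def _interp_crossing(t0, t1, w0, w1, threshold):
    if w1 == w0:
        return t1
    frac = (threshold - w0) / (w1 - w0)
    return t0 + min(max(frac, 0.0), 1.0) * (t1 - t0)


def first_crossing(times, omega, threshold: float) -> float:
    """First time Omega reaches ``threshold``; NaN when never reached.
    Linear interpolation between samples; an exact hit returns that time."""
    times = np.asarray(times, dtype=float)
    omega = np.asarray(omega, dtype=float)
    idx = np.nonzero(omega >= threshold)[0]
    if idx.size == 0:
        return math.nan
    k = int(idx[0])
    if k == 0 or omega[k] == threshold:
        return float(times[k])
    return float(
        _interp_crossing(times[k - 1], times[k], omega[k - 1], omega[k], threshold)
    )


def burn_times(result, params: BurnModelParams) -> tuple[float, float, float]:
    """(t_1st, t_2nd, t_3rd) from a SimulationResult's interface series."""
    frames = getattr(result, "frames", None)
    if frames is None or "omega_ed" not in frames or "omega_ds" not in frames:
        raise ValueError("result lacks interface damage series")
    t = frames["time"].to_numpy()
    w_ed = frames["omega_ed"].to_numpy()
    w_ds = frames["omega_ds"].to_numpy()
    return (
        first_crossing(t, w_ed, params.omega_first_degree),
        first_crossing(t, w_ed, params.omega_second_degree),
        first_crossing(t, w_ds, params.omega_third_degree),
    )
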