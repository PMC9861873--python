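"""Exposure geometry, view factors, incident radiation and surface exchange.

The heat source and the clothed body segment are modelled as two coaxial
parallel discs.  The body moves along the axis, so the source-body distance
and hence the view factor vary in time.  Radiation penetrates the outer
shell following Beer's law; the front face additionally exchanges heat with
ambient air by natural convection (Churchill-Chu vertical plate), and the
thermal-liner back face exchanges radiation with the skin across the air gap
through a grey two-surface enclosure.

Sign convention: fluxes are positive toward the skin (+x, source at x < 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import materials

__all__ = [
    "SIGMA",
    "ExposureGeometry",
    "ConvectionModel",
    "GapRadiationModel",
    "distance_at",
    "view_factor_coaxial_disks",
    "reciprocity_and_complement",
    "incident_radiation",
    "beer_transmitted",
    "beer_absorbed",
    "natural_convection_h",
    "gap_radiative_flux",
]

logger = logging.getLogger("tppsim.radiation")

#: Stefan-Boltzmann constant, W/(m^2 K^4)
SIGMA = 5.67e-8

TRAJECTORY_MODES = ("static", "enter", "enter_exit_hold")


@dataclass
class ExposureGeometry:
    """Source/body disc geometry, emissivities and the motion trajectory.

    ``trajectory_mode``:

    * ``static`` - body fixed at ``x_max``;
    * ``enter`` - body approaches the source at speed ``v`` and stays at
      ``x_min`` once it arrives;
    * ``enter_exit_hold`` - approach to ``x_min``, immediate retreat at the
      same speed, then hold at ``x_max``.
    """

    r_hs: float = 0.1          # heat-source disc radius, m
    r_shell: float = 0.1       # clothed-body disc radius, m
    x_max: float = 0.3         # start distance, m
    x_min: float = 5e-5        # closest distance, m
    v: float = 0.0             # body speed, m/s
    trajectory_mode: str = "static"
    T_hs: float = 1000.0       # source temperature, K
    T_amb: float = 300.0       # ambient temperature, K
    eps_hs: float = 0.9        # source emissivity
    eps_g: float = 0.02        # hot-gas emissivity (re-radiation screening)
    eps_shell: float = 0.9     # outer-shell surface emissivity

    def __post_init__(self):
        if self.trajectory_mode not in TRAJECTORY_MODES:
            raise ValueError(
                f"trajectory_mode must be one of {TRAJECTORY_MODES}"
            )
        if not 0.0 < self.x_min < self.x_max:
            raise ValueError("need 0 < x_min < x_max")
        if self.r_hs <= 0.0 or self.r_shell <= 0.0:
            raise ValueError("disc radii must be positive")
        for name in ("eps_hs", "eps_g", "eps_shell"):
            e = getattr(self, name)
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.trajectory_mode != "static" and self.v <= 0.0:
            raise ValueError("moving trajectories need a positive speed v")

    @property
    def A_hs(self) -> float:
        return math.pi * self.r_hs**2

    @property
    def A_fab(self) -> float:
        return math.pi * self.r_shell**2


def distance_at(t: float, geom: ExposureGeometry) -> float:
    """Instantaneous source-body distance d(t), m."""
    if t < 0.0:
        raise ValueError("time must be nonnegative")
    if geom.trajectory_mode == "static":
        return geom.x_max
    t_arr = (geom.x_max - geom.x_min) / geom.v
    if geom.trajectory_mode == "enter":
        return max(geom.x_max - geom.v * t, geom.x_min)
    # enter_exit_hold
    if t <= t_arr:
        return geom.x_max - geom.v * t
    if t <= 2.0 * t_arr:
        return geom.x_min + geom.v * (t - t_arr)
    return geom.x_max


def view_factor_coaxial_disks(d: float, r_source: float, r_target: float) -> float:
    """View factor from a disc of radius ``r_source`` to a coaxial parallel
    disc of radius ``r_target`` at separation ``d`` (closed form)."""
    if d <= 0.0:
        raise ValueError("separation must be positive")
    if r_source <= 0.0 or r_target <= 0.0:
        raise ValueError("radii must be positive")
    R1 = r_source / d
    R2 = r_target / d
    S = 1.0 + (1.0 + R2**2) / R1**2
    disc = S**2 - 4.0 * (R2 / R1) ** 2
    F = 0.5 * (S - math.sqrt(max(disc, 0.0)))
    return min(max(F, 0.0), 1.0)


def reciprocity_and_complement(
    F_shell_hs: float, A_fab: float, A_hs: float
) -> tuple[float, float]:
    """(F_hs_shell, F_shell_amb) from F_shell_hs by reciprocity/closure."""
    if not 0.0 <= F_shell_hs <= 1.0:
        raise ValueError("view factor must lie in [0, 1]")
    if A_fab <= 0.0 or A_hs <= 0.0:
        raise ValueError("areas must be positive")
    F_hs_shell = F_shell_hs * A_fab / A_hs
    if F_hs_shell > 1.0 + 1e-12:
        raise ValueError(
            f"reciprocity gives F_hs_shell={F_hs_shell:.4f} > 1: "
            "inconsistent geometry"
        )
    return min(F_hs_shell, 1.0), 1.0 - F_shell_hs


def incident_radiation(
    T_hs: float,
    T_shell: float,
    T_amb: float,
    F_hs_shell: float,
    F_shell_amb: float,
    geom: ExposureGeometry,
) -> float:
    """Net radiant flux arriving at the outer shell surface, W/m^2.

    Source exchange minus re-radiation to the (partly gas-screened)
    surroundings; may be negative when the shell outglows the source.
    """
    if min(T_hs, T_shell, T_amb) <= 0.0:
        raise ValueError("temperatures must be positive")
    gain = (
        F_hs_shell
        * SIGMA
        * (geom.eps_hs * T_hs**4 - geom.eps_shell * T_shell**4)
        * geom.A_hs
        / geom.A_fab
    )
    loss = (
        SIGMA
        * geom.eps_shell
        * F_shell_amb
        * (1.0 - geom.eps_g)
        * (T_shell**4 - T_amb**4)
    )
    return gain - loss


def beer_transmitted(q_rad: float, gamma: float, x) -> float | np.ndarray:
    """Radiant flux surviving to depth x in an absorbing layer, W/m^2."""
    if gamma < 0.0:
        raise ValueError("extinction coefficient must be nonnegative")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0):
        raise ValueError("depth must be nonnegative")
    out = q_rad * np.exp(-gamma * x)
    return float(out) if out.ndim == 0 else out


def beer_absorbed(q_rad: float, gamma: float, x) -> float | np.ndarray:
    """Radiant flux absorbed between the surface and depth x, W/m^2.

    Complements :func:`beer_transmitted` exactly: absorbed + transmitted
    equals the incident flux for every depth.
    """
    return q_rad - beer_transmitted(q_rad, gamma, x)


@dataclass
class ConvectionModel:
    """Natural convection at the front face (Churchill-Chu vertical plate).

    Leave ``beta``/``a``/``nu`` as ``None`` to evaluate air-film properties
    at the film temperature (T_shell + T_amb)/2 using simple power-law fits
    for air; supply constants to pin them.
    """

    g: float = 9.81            # m/s^2
    Pr: float = 0.707          # Prandtl number of air
    L_f: float = 0.1           # characteristic plate length, m (fixed)
    beta: float | None = None  # 1/K; default 1/T_film (ideal gas)
    a: float | None = None     # thermal diffusivity, m^2/s
    nu: float | None = None    # kinematic viscosity, m^2/s
    nu_ref: float = 1.589e-5   # air kinematic viscosity at 300 K, m^2/s

    def film_properties(self, T_film: float) -> tuple[float, float, float]:
        """(beta, a, nu) at the film temperature."""
        beta = self.beta if self.beta is not None else 1.0 / T_film
        nu = (
            self.nu
            if self.nu is not None
            else self.nu_ref * (T_film / 300.0) ** 1.7
        )
        a = self.a if self.a is not None else nu / self.Pr
        return beta, a, nu


def natural_convection_h(
    T_shell: float,
    T_amb: float,
    conv: ConvectionModel,
    k_air_at_film: float | None = None,
) -> float:
    """Convective coefficient h, W/(m^2 K), from the Churchill-Chu
    correlation.

    The low-Ra branch (Nu = 0.68 + 0.67 Ra^(1/4) / psi) holds for
    1e-1 < Ra < 1e9; Ra > 1e9 uses the squared turbulent form
    Nu = (0.825 + 0.387 Ra^(1/6) / phi)^2.
    """
    T_film = 0.5 * (T_shell + T_amb)
    beta, a, nu = conv.film_properties(T_film)
    if min(conv.g, beta, a, nu, conv.Pr, conv.L_f) <= 0.0:
        raise ValueError("convection constants must be positive")
    Ra = conv.g * beta * abs(T_shell - T_amb) * conv.L_f**3 / (a * nu)
    if 0.0 < Ra < 1e-1:
        logger.warning("Ra=%.3g below laminar-branch validity; using it anyway", Ra)
    if Ra <= 1e9:
        psi = (1.0 + (0.492 / conv.Pr) ** (9.0 / 16.0)) ** (4.0 / 9.0)
        Nu = 0.68 + 0.67 * Ra**0.25 / psi
    else:
        logger.debug("Churchill-Chu turbulent branch, Ra=%.3g", Ra)
        phi = (1.0 + (0.492 / conv.Pr) ** (9.0 / 16.0)) ** (8.0 / 27.0)
        Nu = (0.825 + 0.387 * Ra ** (1.0 / 6.0) / phi) ** 2
    if k_air_at_film is None:
        k_air_at_film = materials.k_air(T_film)
    return Nu * k_air_at_film / conv.L_f


@dataclass
class GapRadiationModel:
    """Grey enclosure between the thermal-liner back face and the skin."""

    eps_therm: float = 0.9     # liner back-face emissivity
    eps_skin: float = 0.94     # skin emissivity
    F_therm_skin: float = 1.0  # liner->skin view factor (parallel plates)
    kappa_air: float = 5.0     # gap radiation absorption coefficient, 1/m

    def __post_init__(self):
        if not 0.0 < self.eps_therm <= 1.0 or not 0.0 < self.eps_skin <= 1.0:
            raise ValueError("enclosure emissivities must lie in (0, 1]")
        if not 0.0 < self.F_therm_skin <= 1.0:
            raise ValueError("view factor must lie in (0, 1]")
        if self.kappa_air < 0.0:
            raise ValueError("absorption coefficient must be nonnegative")


def gap_radiative_flux(
    T_therm: float, T_epi: float, gap: GapRadiationModel
) -> float:
    """Net radiative flux leaving the liner back face toward the skin,
    W/m^2 (three-resistance grey enclosure)."""
    if T_therm <= 0.0 or T_epi <= 0.0:
        raise ValueError("temperatures must be positive")
    denom = (
        (1.0 - gap.eps_therm) / gap.eps_therm
        + 1.0 / gap.F_therm_skin
        + (1.0 - gap.eps_skin) / gap.eps_skin
    )
    return SIGMA * (T_therm**4 - T_epi**4) / denom
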