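"""Scenario definition, packaged presets, source calibration, sweeps.

A :class:`Scenario` bundles everything one run needs: the fabric and skin
stacks, gap motion and enclosure radiation, exposure geometry, convection
constants, solver settings and burn kinetics.  Exposure levels are stated as
a nominal incident flux (8.5 or 83 kW/m^2); :func:`calibrate_source` backs
out the source temperature that delivers that flux onto a cold garment at
the start distance.
"""

from __future__ import annotations

import copy
import math
from dataclasses import asdict, dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .burn import BurnModelParams, InterfaceKinetics
from .gap import GapMotion
from .materials import AirProperties, FabricStack, LayerProperties, SkinStack
from .radiation import (
    ConvectionModel,
    ExposureGeometry,
    GapRadiationModel,
    incident_radiation,
    reciprocity_and_complement,
    view_factor_coaxial_disks,
)

__all__ = [
    "Scenario",
    "SweepSpec",
    "calibrate_source",
    "builtin",
    "builtin_labels",
    "speed_scenario",
    "load_scenario",
    "save_scenario",
    "run_sweep",
    "grid_independence",
    "load_defaults",
]

SPEED_LEVELS = ("low", "medium", "high")


def load_defaults() -> dict:
    """Packaged default parameter sets (deep copy; safe to mutate)."""
    text = resources.files("tppsim.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


@dataclass
class Scenario:
    """One fully specified simulation."""

    label: str
    fabric: FabricStack
    skin: SkinStack
    gap_motion: GapMotion
    gap_radiation: GapRadiationModel
    geometry: ExposureGeometry
    convection: ConvectionModel
    air: AirProperties = field(default_factory=AirProperties)
    burn: BurnModelParams = field(default_factory=BurnModelParams)
    dt: float = 0.1
    dx: float = 5e-6
    duration: float = 300.0

    def __post_init__(self):
        if self.duration < 0.0:
            raise ValueError("duration must be nonnegative")
        if self.dt <= 0.0 or self.dx <= 0.0:
            raise ValueError("dt and dx must be positive")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "fabric": [asdict(l) for l in self.fabric.layers],
            "skin": {
                "layers": [asdict(l) for l in self.skin.layers],
                "basal_temperature": self.skin.basal_temperature,
                "surface_initial_temperature": self.skin.surface_initial_temperature,
                "emissivity": self.skin.emissivity,
            },
            "gap_motion": asdict(self.gap_motion),
            "gap_radiation": asdict(self.gap_radiation),
            "geometry": asdict(self.geometry),
            "convection": asdict(self.convection),
            "air": asdict(self.air),
            "burn": {
                "epidermis_dermis": asdict(self.burn.epidermis_dermis),
                "dermis_subcutaneous": asdict(self.burn.dermis_subcutaneous),
                "omega_first_degree": self.burn.omega_first_degree,
                "omega_second_degree": self.burn.omega_second_degree,
                "omega_third_degree": self.burn.omega_third_degree,
                "gas_constant": self.burn.gas_constant,
            },
            "solver": {"dt": self.dt, "dx": self.dx, "duration": self.duration},
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        try:
            fabric = FabricStack([LayerProperties(**l) for l in d["fabric"]])
            sk = d["skin"]
            skin = SkinStack(
                layers=[LayerProperties(**l) for l in sk["layers"]],
                basal_temperature=sk.get("basal_temperature", 306.65),
                surface_initial_temperature=sk.get(
                    "surface_initial_temperature", 305.65
                ),
                emissivity=sk.get("emissivity", 0.94),
            )
            burn_d = d.get("burn", {})
            burn = BurnModelParams(
                epidermis_dermis=InterfaceKinetics(**burn_d["epidermis_dermis"])
                if "epidermis_dermis" in burn_d
                else BurnModelParams().epidermis_dermis,
                dermis_subcutaneous=InterfaceKinetics(**burn_d["dermis_subcutaneous"])
                if "dermis_subcutaneous" in burn_d
                else BurnModelParams().dermis_subcutaneous,
                omega_first_degree=burn_d.get("omega_first_degree", 0.53),
                omega_second_degree=burn_d.get("omega_second_degree", 1.0),
                omega_third_degree=burn_d.get("omega_third_degree", 1.0),
                gas_constant=burn_d.get("gas_constant", 8.31),
            )
            solver_d = d.get("solver", {})
            return cls(
                label=d["label"],
                fabric=fabric,
                skin=skin,
                gap_motion=GapMotion(**d["gap_motion"]),
                gap_radiation=GapRadiationModel(**d["gap_radiation"]),
                geometry=ExposureGeometry(**d["geometry"]),
                convection=ConvectionModel(**d.get("convection", {})),
                air=AirProperties(**d.get("air", {})),
                burn=burn,
                dt=solver_d.get("dt", 0.1),
                dx=solver_d.get("dx", 5e-6),
                duration=solver_d.get("duration", 300.0),
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"malformed scenario definition: {exc!r}") from exc


def save_scenario(scenario: Scenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=False)


def load_scenario(path) -> Scenario:
    """Parse and validate a scenario file (YAML or JSON-compatible)."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError(f"scenario file {path!r} does not contain a mapping")
    return Scenario.from_dict(d)


# ---------------------------------------------------------------------------
# source calibration
# ---------------------------------------------------------------------------

def calibrate_source(
    geometry: ExposureGeometry,
    target_flux: float,
    at_distance: float | None = None,
    rtol: float = 1e-3,
) -> ExposureGeometry:
    """Return a copy of ``geometry`` whose source temperature delivers
    ``target_flux`` onto a cold garment (shell at ambient) at
    ``at_distance`` (default: the start distance), to 0.1 %."""
    if target_flux <= 0.0:
        raise ValueError("target flux must be positive")
    d = geometry.x_max if at_distance is None else at_distance
    F_shell_hs = view_factor_coaxial_disks(d, geometry.r_shell, geometry.r_hs)
    F_hs_shell, F_shell_amb = reciprocity_and_complement(
        F_shell_hs, geometry.A_fab, geometry.A_hs
    )

    def residual(T_hs):
        g = replace(geometry, T_hs=T_hs)
        return (
            incident_radiation(
                T_hs, geometry.T_amb, geometry.T_amb, F_hs_shell, F_shell_amb, g
            )
            - target_flux
        )

    T_lo, T_hi = geometry.T_amb, 6000.0
    if residual(T_hi) < 0.0:
        raise ValueError(
            f"target flux {target_flux} W/m^2 unattainable below {T_hi} K "
            "with this geometry"
        )
    T_hs = brentq(residual, T_lo, T_hi, xtol=1e-6, rtol=1e-12)
    achieved = target_flux + residual(T_hs)
    if abs(achieved - target_flux) > rtol * target_flux:
        raise RuntimeError("source calibration failed to converge")
    return replace(geometry, T_hs=T_hs)


# ---------------------------------------------------------------------------
# built-in scenarios
# ---------------------------------------------------------------------------

def _base_components(defaults: dict, fabric_set: str = "three_layer_nomex"):
    fabric = FabricStack(
        [LayerProperties(**l) for l in defaults["fabric"][fabric_set]]
    )
    sk = defaults["skin"]["torvi_three_layer"]
    skin = SkinStack(
        layers=[LayerProperties(**l) for l in sk["layers"]],
        basal_temperature=sk["basal_temperature"],
        surface_initial_temperature=sk["surface_initial_temperature"],
        emissivity=sk["emissivity"],
    )
    gap_rad = GapRadiationModel(**defaults["gap_radiation"])
    conv = ConvectionModel(**defaults["convection"])
    air = AirProperties(**defaults["air"])
    return fabric, skin, gap_rad, conv, air


def _make_geometry(
    defaults: dict, flux: float, trajectory: str, v: float,
    eps_shell: float, overrides: dict | None = None,
):
    geo = dict(defaults["geometry"])
    if overrides:
        geo.update(overrides)
    g = ExposureGeometry(
        **geo,
        trajectory_mode=trajectory,
        v=v,
        T_hs=1000.0,
        eps_shell=eps_shell,
    )
    return calibrate_source(g, flux)


def _scenario(
    defaults,
    label,
    flux,
    trajectory="static",
    v=0.0,
    amplitude=0.0,
    frequency=0.0,
    duration=None,
    fabric_set="three_layer_nomex",
    geometry_overrides=None,
):
    fabric, skin, gap_rad, conv, air = _base_components(defaults, fabric_set)
    geometry = _make_geometry(
        defaults, flux, trajectory, v, fabric.shell.emissivity, geometry_overrides
    )
    gm_d = defaults["gap_motion"]
    gap_motion = GapMotion(
        x0=gm_d["x0"], amplitude=amplitude, frequency=frequency,
        floor=gm_d["floor"],
    )
    sol = defaults["solver"]
    return Scenario(
        label=label,
        fabric=fabric,
        skin=skin,
        gap_motion=gap_motion,
        gap_radiation=gap_rad,
        geometry=geometry,
        convection=conv,
        air=air,
        dt=sol["dt"],
        dx=sol["dx"],
        duration=sol["duration"] if duration is None else duration,
    )


def speed_scenario(
    level: str,
    amplitude: float = 0.0015,
    defaults: dict | None = None,
    label: str | None = None,
) -> Scenario:
    """Enter(/exit) scenario at a named body-movement speed level.

    Levels map to arrival times 300 / 100 / 60 s at the closest point and
    gap-motion frequencies 0.25 / 0.5 / 1 Hz; low speed enters and stays,
    medium and high return to the start distance and hold there.
    """
    if level not in SPEED_LEVELS:
        raise ValueError(f"speed level must be one of {SPEED_LEVELS}")
    defaults = defaults or load_defaults()
    spec = defaults["speed_levels"][level]
    geom_d = defaults["geometry"]
    v = (geom_d["x_max"] - geom_d["x_min"]) / spec["arrival_time"]
    return _scenario(
        defaults,
        label or f"enter_{level}_speed",
        defaults["exposure_levels"]["low_level"],
        trajectory=spec["trajectory"],
        v=v,
        amplitude=amplitude,
        frequency=spec["frequency"] if amplitude > 0.0 else 0.0,
    )


_BUILTIN_LABELS = (
    "lowlevel_stationary",
    "flashfire_stationary",
    "flashfire_dynamic",
    "enter_low_speed",
    "enter_medium_speed",
    "enter_high_speed",
)


def builtin_labels() -> tuple[str, ...]:
    return _BUILTIN_LABELS


def builtin(label: str) -> Scenario:
    """Construct a packaged scenario by name.

    * ``lowlevel_stationary`` - 8.5 kW/m^2, 300 s, static 3 mm gap.
    * ``flashfire_stationary`` / ``flashfire_dynamic`` - 83 kW/m^2, 3 mm gap,
      the dynamic variant breathing at 0.5 Hz with 1.5 mm amplitude.
    * ``enter_{low,medium,high}_speed`` - 8.5 kW/m^2 firefighting approach
      from 0.3 m with gap motion at the level's frequency, amplitude 1.5 mm.
    """
    defaults = load_defaults()
    flux_low = defaults["exposure_levels"]["low_level"]
    flux_flash = defaults["exposure_levels"]["flash_fire"]
    if label == "lowlevel_stationary":
        return _scenario(defaults, label, flux_low)
    # Flash-fire bench exposure: a small, very hot source (burner scale,
    # ~2000 K after calibration) rather than the large far-field panel of
    # the firefighting scenarios, and the garment is immersed in luminous
    # flame, so the surrounding hot gas is nearly opaque (eps_g ~ 0.9) and
    # re-radiation to ambient is largely screened.
    flash_geo = {"r_hs": 0.1, "r_shell": 0.1, "eps_g": 0.9}
    if label == "flashfire_stationary":
        return _scenario(
            defaults, label, flux_flash, duration=60.0,
            fabric_set="flash_fire_ensemble", geometry_overrides=flash_geo,
        )
    if label == "flashfire_dynamic":
        return _scenario(
            defaults, label, flux_flash,
            amplitude=0.0015, frequency=0.5, duration=60.0,
            fabric_set="flash_fire_ensemble", geometry_overrides=flash_geo,
        )
    if label in ("enter_low_speed", "enter_medium_speed", "enter_high_speed"):
        level = label.split("_")[1]
        return speed_scenario(level, defaults=defaults, label=label)
    raise ValueError(f"unknown builtin {label!r}; known: {_BUILTIN_LABELS}")


# ---------------------------------------------------------------------------
# sweeps and grid independence
# ---------------------------------------------------------------------------

@dataclass
class SweepSpec:
    """A one-axis parameter sweep over a base scenario.

    ``axis`` is one of ``amplitude`` (gap-motion amplitude, m),
    ``frequency`` (Hz) or ``speed_level`` (low/medium/high; rebuilds the
    trajectory and frequency from the packaged level definitions).
    """

    base: Scenario
    axis: str
    values: list

    def __post_init__(self):
        if self.axis not in ("amplitude", "frequency", "speed_level"):
            raise ValueError("axis must be amplitude, frequency or speed_level")
        if not self.values:
            raise ValueError("sweep needs at least one value")

    def scenario_for(self, value) -> Scenario:
        if self.axis == "speed_level":
            return speed_scenario(value, amplitude=self.base.gap_motion.amplitude)
        gm = self.base.gap_motion
        if self.axis == "amplitude":
            gm = GapMotion(gm.x0, float(value), gm.frequency, gm.floor)
        else:
            gm = GapMotion(gm.x0, gm.amplitude, float(value), gm.floor)
        out = copy.deepcopy(self.base)
        out.gap_motion = gm
        out.label = f"{self.base.label}[{self.axis}={value}]"
        return out


def run_sweep(spec: SweepSpec, progress: bool = False) -> pd.DataFrame:
    """One simulation per axis value; burn times and peak temperatures per
    row.  Failures are recorded (error column) and the sweep continues."""
    from .solver import run_simulation

    rows = []
    for value in spec.values:
        row = {spec.axis: value}
        try:
            res = run_simulation(spec.scenario_for(value), progress=progress)
            row.update(
                t_first_degree=res.burn_times["first_degree"],
                t_second_degree=res.burn_times["second_degree"],
                t_third_degree=res.burn_times["third_degree"],
                peak_T_epidermis_dermis=float(
                    res.frames["T_epidermis_dermis"].max()
                ),
                peak_T_dermis_subcutaneous=float(
                    res.frames["T_dermis_subcutaneous"].max()
                ),
                error="",
            )
        except Exception as exc:  # keep sweeping
            row.update(
                t_first_degree=math.nan, t_second_degree=math.nan,
                t_third_degree=math.nan,
                peak_T_epidermis_dermis=math.nan,
                peak_T_dermis_subcutaneous=math.nan,
                error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def grid_independence(
    scenario: Scenario, dt_list, dx_list
) -> pd.DataFrame:
    """Self-convergence of the dermis-subcutaneous temperature trace.

    Runs the scenario once per (dt, dx) pair (the lists are zipped) and
    reports, for each pair, the maximum absolute deviation of the trace
    from the finest pair's trace, compared on the coarser time grid.
    """
    from .solver import run_simulation

    dt_list, dx_list = list(dt_list), list(dx_list)
    if not dt_list or not dx_list:
        raise ValueError("dt and dx lists must be nonempty")
    if len(dt_list) != len(dx_list):
        raise ValueError("dt and dx lists must pair up")
    traces = []
    for dt, dx in zip(dt_list, dx_list):
        scn = copy.deepcopy(scenario)
        scn.dt, scn.dx = float(dt), float(dx)
        res = run_simulation(scn)
        traces.append(
            (dt, dx, res.frames["time"].to_numpy(),
             res.frames["T_dermis_subcutaneous"].to_numpy())
        )
    # finest = smallest dt (ties: smallest dx)
    ref = min(traces, key=lambda r: (r[0], r[1]))
    rows = []
    for dt, dx, t, T in traces:
        T_ref = np.interp(t, ref[2], ref[3])
        rows.append(
            {"dt": dt, "dx": dx,
             "max_deviation_K": float(np.max(np.abs(T - T_ref)))}
        )
    return pd.DataFrame(rows)
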