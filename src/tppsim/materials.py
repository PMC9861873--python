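"""Thermophysical properties of protective-fabric layers, air and skin.

The outer shell of a firefighters' garment is a Nomex-type woven fabric whose
effective conductivity is a volume-fraction blend of the fibre and the air
entrapped in the weave (80 % air / 20 % fibre).  Both constituent
conductivities follow two-branch linear laws in temperature with the branch
split at 700 K.  Everything here is strict SI; temperatures are kelvin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np

__all__ = [
    "k_fiber",
    "k_air",
    "k_shell",
    "extinction_coefficient",
    "resolve_conductivity",
    "CONDUCTIVITY_LAWS",
    "LayerProperties",
    "FabricStack",
    "SkinStack",
    "AirProperties",
]


def _check_temperature(T):
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0.0):
        raise ValueError("temperature must be positive (kelvin)")
    return T


def k_fiber(T):
    """Conductivity of the shell fibre, W/(m K).

    Linear in T below 700 K, constant 1 W/(m K) above; T = 700 K is assigned
    to the linear branch (left-continuous).
    """
    T = _check_temperature(T)
    out = np.where(T <= 700.0, 0.13 + 0.0018 * (T - 300.0), 1.0)
    return float(out) if out.ndim == 0 else out


def k_air(T):
    """Conductivity of air, W/(m K); two linear branches split at 700 K."""
    T = _check_temperature(T)
    out = np.where(
        T <= 700.0,
        0.026 + 0.000068 * (T - 300.0),
        0.053 + 0.000054 * (T - 700.0),
    )
    return float(out) if out.ndim == 0 else out


def k_shell(T):
    """Effective shell conductivity: 0.8 * k_air(T) + 0.2 * k_fiber(T)."""
    return 0.8 * k_air(T) + 0.2 * k_fiber(T)


def extinction_coefficient(tau: float, thickness: float) -> float:
    """Beer's-law extinction coefficient, 1/m, from transmissivity and depth.

    gamma = -ln(tau) / L for a layer of thickness L transmitting a fraction
    tau of normally incident radiation.
    """
    if not 0.0 < tau <= 1.0:
        raise ValueError(f"transmissivity must be in (0, 1], got {tau}")
    if thickness <= 0.0:
        raise ValueError(f"thickness must be positive, got {thickness}")
    return -math.log(tau) / thickness


#: named temperature-dependent conductivity laws usable in layer configs
CONDUCTIVITY_LAWS: dict[str, Callable] = {
    "nomex_shell": k_shell,
    "air": k_air,
    "fiber": k_fiber,
}


def resolve_conductivity(spec: Union[float, str, Callable]) -> Callable:
    """Turn a conductivity spec (constant, law name or callable) into k(T)."""
    if callable(spec):
        return spec
    if isinstance(spec, str):
        try:
            return CONDUCTIVITY_LAWS[spec]
        except KeyError:
            raise ValueError(
                f"unknown conductivity law {spec!r}; "
                f"known: {sorted(CONDUCTIVITY_LAWS)}"
            ) from None
    k = float(spec)
    if k <= 0.0:
        raise ValueError("constant conductivity must be positive")
    return lambda T, _k=k: np.full_like(np.asarray(T, dtype=float), _k)


@dataclass
class LayerProperties:
    """Geometry and thermophysical constants of one homogeneous layer.

    ``conductivity`` is either a constant in W/(m K) or the name of a law in
    :data:`CONDUCTIVITY_LAWS` (the shell normally uses ``"nomex_shell"``).
    ``transmissivity`` is only meaningful for the outer shell and fixes its
    Beer's-law extinction coefficient.
    """

    name: str
    thickness: float
    density: float
    specific_heat: float
    conductivity: Union[float, str]
    emissivity: float | None = None
    transmissivity: float | None = None

    def __post_init__(self):
        if self.thickness <= 0.0:
            raise ValueError(f"{self.name}: thickness must be positive")
        if self.density <= 0.0:
            raise ValueError(f"{self.name}: density must be positive")
        if self.specific_heat <= 0.0:
            raise ValueError(f"{self.name}: specific heat must be positive")
        if self.emissivity is not None and not 0.0 <= self.emissivity <= 1.0:
            raise ValueError(f"{self.name}: emissivity must lie in [0, 1]")
        if self.transmissivity is not None and not 0.0 < self.transmissivity <= 1.0:
            raise ValueError(f"{self.name}: transmissivity must lie in (0, 1]")
        # validate constant conductivities / law names eagerly
        resolve_conductivity(self.conductivity)

    def conductivity_fn(self) -> Callable:
        return resolve_conductivity(self.conductivity)

    @property
    def volumetric_heat_capacity(self) -> float:
        """rho * c_p, J/(m^3 K)."""
        return self.density * self.specific_heat

    @property
    def extinction_coefficient(self) -> float:
        if self.transmissivity is None:
            raise ValueError(f"{self.name}: no transmissivity configured")
        return extinction_coefficient(self.transmissivity, self.thickness)


@dataclass
class FabricStack:
    """Ordered garment layers, outermost first.

    The standard ensemble is outer shell / moisture barrier / thermal liner;
    a single-layer garment (shell only) is also accepted.
    """

    layers: Sequence[LayerProperties]

    def __post_init__(self):
        self.layers = list(self.layers)
        if len(self.layers) not in (1, 3):
            raise ValueError(
                f"fabric stack needs 1 or 3 layers, got {len(self.layers)}"
            )
        shell = self.layers[0]
        if shell.transmissivity is None:
            raise ValueError("outer shell requires a transmissivity")
        if shell.emissivity is None:
            raise ValueError("outer shell requires an emissivity")

    @property
    def shell(self) -> LayerProperties:
        return self.layers[0]

    @property
    def liner(self) -> LayerProperties:
        """Innermost layer (faces the air-gap microenvironment)."""
        return self.layers[-1]

    @property
    def total_thickness(self) -> float:
        return sum(l.thickness for l in self.layers)


@dataclass
class SkinStack:
    """Epidermis / dermis / subcutaneous tissue, outermost first.

    The deep boundary is held at the core-side basal temperature for all
    time; the initial profile is linear from the surface value to the basal
    value.
    """

    layers: Sequence[LayerProperties]
    basal_temperature: float = 306.65
    surface_initial_temperature: float = 305.65
    emissivity: float = 0.94

    def __post_init__(self):
        self.layers = list(self.layers)
        if len(self.layers) != 3:
            raise ValueError("skin stack needs exactly 3 layers")
        if not 0.0 < self.emissivity <= 1.0:
            raise ValueError("skin emissivity must lie in (0, 1]")

    @property
    def total_thickness(self) -> float:
        return sum(l.thickness for l in self.layers)


@dataclass
class AirProperties:
    """Bulk air in the microenvironment gap (conductivity comes from k_air)."""

    density: float = 1.177       # kg/m^3 at ~300 K
    specific_heat: float = 1006.0  # J/(kg K)

    def __post_init__(self):
        if self.density <= 0.0 or self.specific_heat <= 0.0:
            raise ValueError("air properties must be positive")

    @property
    def volumetric_heat_capacity(self) -> float:
        return self.density * self.specific_heat
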