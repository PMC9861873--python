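"""Air-gap (microenvironment) motion and the 1D composite mesh.

The gap between the thermal-liner back face and the skin breathes
sinusoidally as the wearer moves; its node count stays fixed while the node
spacing rescales uniformly with the instantaneous thickness.  Fabric and
skin nodes never move relative to their layers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .materials import FabricStack, SkinStack

__all__ = ["GapMotion", "Mesh", "gap_thickness", "build_mesh", "remesh_gap"]

logger = logging.getLogger("tppsim.gap")


@dataclass
class GapMotion:
    """Sinusoidal gap thickness x(t) = x0 + amplitude * sin(2 pi f t),
    clamped below at ``floor`` so a conduction path always remains."""

    x0: float = 0.003        # mean thickness, m
    amplitude: float = 0.0   # m
    frequency: float = 0.0   # 1/s
    floor: float = 1e-4      # minimum admissible thickness, m

    def __post_init__(self):
        if self.x0 <= 0.0:
            raise ValueError("mean gap thickness must be positive")
        if self.amplitude < 0.0 or self.amplitude >= self.x0:
            raise ValueError("need 0 <= amplitude < x0 (gap must not invert)")
        if self.frequency < 0.0:
            raise ValueError("frequency must be nonnegative")
        if self.floor <= 0.0:
            raise ValueError("floor must be positive")
        self._clamp_warned = False

    def thickness(self, t: float) -> float:
        return gap_thickness(t, self)


def gap_thickness(t: float, gm: GapMotion) -> float:
    """Instantaneous gap thickness, m, clamped below at ``gm.floor``."""
    if t < 0.0:
        raise ValueError("time must be nonnegative")
    x = gm.x0 + gm.amplitude * math.sin(2.0 * math.pi * gm.frequency * t)
    if x < gm.floor:
        if not gm._clamp_warned:
            logger.warning(
                "gap thickness clamped at floor %.3g m (first at t=%.3f s)",
                gm.floor, t,
            )
            gm._clamp_warned = True
        return gm.floor
    return x


@dataclass
class Mesh:
    """Node layout over fabric + gap + skin.

    ``positions`` are node coordinates with x = 0 at the exposed shell
    surface; interfaces between regions are owned by a single shared node.
    ``interval_region`` labels each interval (between consecutive nodes)
    with an index into ``region_names``; the gap region keeps a constant
    node count and uniform spacing that rescales with thickness.
    """

    positions: np.ndarray
    interval_region: np.ndarray     # int code per interval
    region_names: list[str]         # e.g. shell, moisture_barrier, ..., gap, ...
    boundaries: dict[str, int]      # named node indices
    gap_intervals: slice            # interval index range of the gap
    gap_nodes: slice                # node index range incl. both interfaces

    @property
    def n_nodes(self) -> int:
        return self.positions.size

    @property
    def h(self) -> np.ndarray:
        return np.diff(self.positions)

    @property
    def gap_thickness(self) -> float:
        i0, i1 = self.gap_nodes.start, self.gap_nodes.stop - 1
        return float(self.positions[i1] - self.positions[i0])

    def validate(self):
        if np.any(np.diff(self.positions) <= 0.0):
            raise ValueError("mesh positions must be strictly increasing")


def _layer_intervals(thickness: float, dx: float, name: str) -> int:
    n = round(thickness / dx)
    if n < 2:
        raise ValueError(
            f"layer {name!r} ({thickness:g} m) under-resolved at dx={dx:g} m"
        )
    if abs(n * dx - thickness) > 0.51 * dx:
        raise ValueError(
            f"dx={dx:g} m does not divide layer {name!r} ({thickness:g} m) "
            "to within one node"
        )
    return n


def build_mesh(
    fabric: FabricStack, skin: SkinStack, gap: GapMotion, dx: float
) -> Mesh:
    """Lay out nodes at spacing ``dx`` in fabric and skin and
    round(x0/dx) uniform intervals across the gap at its mean thickness."""
    if dx <= 0.0:
        raise ValueError("dx must be positive")
    region_names: list[str] = []
    counts: list[int] = []
    widths: list[float] = []
    for layer in fabric.layers:
        region_names.append(layer.name)
        counts.append(_layer_intervals(layer.thickness, dx, layer.name))
        widths.append(layer.thickness)
    n_gap = round(gap.x0 / dx)
    if n_gap < 2:
        raise ValueError("gap under-resolved at this dx")
    region_names.append("gap")
    counts.append(n_gap)
    widths.append(gap.x0)
    for layer in skin.layers:
        region_names.append(layer.name)
        counts.append(_layer_intervals(layer.thickness, dx, layer.name))
        widths.append(layer.thickness)

    pieces = [np.array([0.0])]
    interval_region = []
    x0 = 0.0
    boundaries: dict[str, int] = {"shell_front": 0}
    node_count = 1
    n_fabric = len(fabric.layers)
    for r, (n, w) in enumerate(zip(counts, widths)):
        pieces.append(x0 + w * np.arange(1, n + 1) / n)
        interval_region.append(np.full(n, r, dtype=np.int64))
        x0 += w
        node_count += n
        end = node_count - 1
        if r == n_fabric - 1:
            boundaries["fabric_back"] = end       # liner | gap
        elif r == n_fabric:
            boundaries["skin_front"] = end        # gap | epidermis
        elif r == n_fabric + 1:
            boundaries["epidermis_dermis"] = end
        elif r == n_fabric + 2:
            boundaries["dermis_subcutaneous"] = end
    boundaries["skin_back"] = node_count - 1

    positions = np.concatenate(pieces)
    interval_region = np.concatenate(interval_region)
    gi0 = boundaries["fabric_back"]
    gi1 = boundaries["skin_front"]
    mesh = Mesh(
        positions=positions,
        interval_region=interval_region,
        region_names=region_names,
        boundaries=boundaries,
        gap_intervals=slice(gi0, gi1),
        gap_nodes=slice(gi0, gi1 + 1),
    )
    mesh.validate()
    return mesh


def remesh_gap(
    mesh: Mesh, T: np.ndarray, new_thickness: float
) -> tuple[Mesh, np.ndarray]:
    """Rescale the gap to ``new_thickness`` and carry temperatures.

    Gap node positions are mapped affinely onto the new thickness and the
    gap temperature profile is interpolated linearly in the relative gap
    coordinate (material-frame carry); on the uniform gap grid this is an
    exact per-node carry, so an unchanged thickness returns ``T``
    bit-for-bit.  Fabric nodes are untouched; skin nodes translate rigidly.
    """
    if new_thickness <= 0.0:
        raise ValueError("gap thickness must be positive")
    i0 = mesh.gap_nodes.start
    i1 = mesh.gap_nodes.stop - 1
    old = mesh.positions
    L_old = old[i1] - old[i0]
    if new_thickness == L_old:
        return mesh, T
    pos = old.copy()
    n_int = i1 - i0
    xi = np.arange(n_int + 1) / n_int
    pos[i0 : i1 + 1] = old[i0] + new_thickness * xi
    pos[i1 + 1 :] = old[i1 + 1 :] + (new_thickness - L_old)
    # both grids are uniform in the relative gap coordinate, so linear
    # interpolation in that coordinate is an exact per-node carry
    T_new = T
    new_mesh = Mesh(
        positions=pos,
        interval_region=mesh.interval_region,
        region_names=mesh.region_names,
        boundaries=mesh.boundaries,
        gap_intervals=mesh.gap_intervals,
        gap_nodes=mesh.gap_nodes,
    )
    return new_mesh, T_new
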