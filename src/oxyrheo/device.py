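"""Hydraulic model of the branching microfluidic viscometer.

The blood layer of the device is represented as an electrical-analog
resistor circuit: an inlet "pressure dissipater" resistor in series with
two parallel branches, a normoxic bypass channel and the experimental
channel held at a controlled oxygen tension.  At the device Reynolds
numbers (Re << 1) each channel behaves as a linear hydraulic resistor
R = c * eta, where the geometric constant c (units 1/m^3) depends only on
the channel cross-section and length and eta is the effective viscosity
of the fluid in that section.

Resistance formulas are the standard laminar-flow results for square and
shallow rectangular ducts::

    square      (h = w):  R = 12 eta L / (0.422 h^4)
    rectangular (h <= w): R = 12 eta L / [(1 - 0.63 h/w) h^3 w]

The two formulas disagree by a factor 0.422/0.37 ~ 1.14 at h = w, so
square channels must always route through the square formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

__all__ = [
    "ChannelGeometry",
    "HydraulicResistor",
    "DeviceNetwork",
    "FluidState",
    "ShapeError",
    "resistance_square",
    "resistance_rectangular",
    "channel_resistance",
    "geometric_constant",
    "network_resistance",
    "reynolds_number",
]

ShapeTag = Literal["square", "rectangular"]
RoleTag = Literal["inlet_resistor", "bypass", "experimental"]

_SQUARE_RTOL = 1e-9


class ShapeError(ValueError):
    """Channel geometry routed to the wrong resistance formula."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular microchannel cross-section and length, SI units."""

    height_m: float
    width_m: float
    length_m: float
    shape: ShapeTag

    def __post_init__(self) -> None:
        for name in ("height_m", "width_m", "length_m"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(f"ChannelGeometry.{name} must be finite and > 0, got {v!r}")
        if self.shape == "square":
            if abs(self.height_m - self.width_m) / self.height_m >= _SQUARE_RTOL:
                raise ShapeError(
                    f"square channel requires h == w, got h={self.height_m}, w={self.width_m}"
                )
        elif self.shape == "rectangular":
            if self.height_m > self.width_m:
                raise ShapeError(
                    f"rectangular formula is valid only for h <= w, got h={self.height_m} > w={self.width_m}"
                )
        else:
            raise ValueError(f"unknown channel shape {self.shape!r}")

    @property
    def area_m2(self) -> float:
        """Cross-sectional area h*w."""
        return self.height_m * self.width_m

    @property
    def half_height_m(self) -> float:
        """Half the channel height, the length scale of the wall shear rate."""
        return 0.5 * self.height_m


def resistance_square(geometry: ChannelGeometry, viscosity_pa_s: float) -> float:
    """Hydraulic resistance of a square duct, R = 12*eta*L / (0.422 h^4).

    Parameters
    ----------
    geometry
        Channel geometry with ``shape == "square"``.
    viscosity_pa_s
        Dynamic viscosity of the fluid in the channel (Pa s), >= 0.

    Returns
    -------
    float
        Resistance in Pa s / m^3, linear in viscosity and length.
    """
    if geometry.shape != "square":
        raise ShapeError(f"resistance_square requires a square channel, got {geometry.shape!r}")
    if viscosity_pa_s < 0:
        raise ValueError("viscosity must be >= 0")
    h = geometry.height_m
    return 12.0 * viscosity_pa_s * geometry.length_m / (0.422 * h**4)


def resistance_rectangular(geometry: ChannelGeometry, viscosity_pa_s: float) -> float:
    """Hydraulic resistance of a shallow rectangular duct (h <= w).

    R = 12*eta*L / [(1 - 0.63 h/w) h^3 w].  Accurate in the wide-channel
    limit; not valid for square ducts, which use :func:`resistance_square`.
    """
    if geometry.shape != "rectangular":
        raise ShapeError(
            f"resistance_rectangular requires a rectangular channel, got {geometry.shape!r}"
        )
    if viscosity_pa_s < 0:
        raise ValueError("viscosity must be >= 0")
    h, w = geometry.height_m, geometry.width_m
    return 12.0 * viscosity_pa_s * geometry.length_m / ((1.0 - 0.63 * h / w) * h**3 * w)


def channel_resistance(geometry: ChannelGeometry, viscosity_pa_s: float) -> float:
    """Dispatch to the correct resistance formula for the geometry's shape."""
    if geometry.shape == "square":
        return resistance_square(geometry, viscosity_pa_s)
    return resistance_rectangular(geometry, viscosity_pa_s)


def geometric_constant(geometry: ChannelGeometry) -> float:
    """Geometric constant c = R/eta (1/m^3), i.e. the resistance at unit viscosity."""
    return channel_resistance(geometry, 1.0)


@dataclass(frozen=True)
class HydraulicResistor:
    """One resistor of the circuit: a geometric constant plus an optional geometry.

    The constant is all the circuit algebra needs; the geometry (when known)
    additionally enables section shear-rate allocation during rheogram
    inversion.  Configs for real devices may supply only the constant because
    the dissipater geometry is generally proprietary to the mask design.
    """

    role: RoleTag
    c_per_m3: float
    geometry: Optional[ChannelGeometry] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.c_per_m3) and self.c_per_m3 > 0):
            raise ValueError(f"geometric constant must be finite and > 0, got {self.c_per_m3!r}")

    @classmethod
    def from_geometry(cls, role: RoleTag, geometry: ChannelGeometry) -> "HydraulicResistor":
        """Compute and cache c from the channel geometry (R at eta = 1)."""
        return cls(role=role, c_per_m3=geometric_constant(geometry), geometry=geometry)

    @classmethod
    def from_constant(
        cls, role: RoleTag, c_per_m3: float, geometry: Optional[ChannelGeometry] = None
    ) -> "HydraulicResistor":
        return cls(role=role, c_per_m3=c_per_m3, geometry=geometry)

    def resistance(self, viscosity_pa_s: float) -> float:
        if viscosity_pa_s < 0:
            raise ValueError("viscosity must be >= 0")
        return self.c_per_m3 * viscosity_pa_s


@dataclass(frozen=True)
class DeviceNetwork:
    """Fixed circuit topology: inlet resistor in series with (bypass || experimental)."""

    inlet_resistor: HydraulicResistor
    bypass: HydraulicResistor
    experimental: HydraulicResistor

    def __post_init__(self) -> None:
        expected = {
            "inlet_resistor": self.inlet_resistor,
            "bypass": self.bypass,
            "experimental": self.experimental,
        }
        for name, res in expected.items():
            if res.role != name:
                raise ValueError(f"resistor in slot {name!r} has role {res.role!r}")

    @property
    def c1(self) -> float:
        return self.inlet_resistor.c_per_m3

    @property
    def c2(self) -> float:
        return self.bypass.c_per_m3

    @property
    def c3(self) -> float:
        return self.experimental.c_per_m3

    def has_geometries(self) -> bool:
        return all(
            r.geometry is not None for r in (self.inlet_resistor, self.bypass, self.experimental)
        )


def network_resistance(network: DeviceNetwork, eta1: float, eta2: float, eta3: float) -> float:
    """Total hydraulic resistance of the circuit for section viscosities eta1..eta3.

    R_hyd = c1*eta1 + 1 / (1/(c2*eta2) + 1/(c3*eta3))

    Degree-1 homogeneous in (eta1, eta2, eta3); the parallel section is
    bounded above by min(c2*eta2, c3*eta3).
    """
    for eta in (eta1, eta2, eta3):
        if not (math.isfinite(eta) and eta > 0):
            raise ValueError(f"section viscosities must be finite and > 0, got {eta!r}")
    r2 = network.c2 * eta2
    r3 = network.c3 * eta3
    return network.c1 * eta1 + (r2 * r3) / (r2 + r3)


@dataclass(frozen=True)
class FluidState:
    """Bulk fluid properties for a Reynolds-number check."""

    density_kg_m3: float
    viscosity_pa_s: float
    velocity_m_s: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.density_kg_m3) and self.density_kg_m3 > 0):
            raise ValueError("density must be > 0")
        if not (math.isfinite(self.viscosity_pa_s) and self.viscosity_pa_s > 0):
            raise ValueError("viscosity must be > 0")
        if not (math.isfinite(self.velocity_m_s) and self.velocity_m_s >= 0):
            raise ValueError("velocity must be >= 0")


def reynolds_number(fluid: FluidState, hydraulic_diameter_m: float) -> float:
    """Re = rho * u * L / mu for the channel hydraulic diameter L.

    The device operates deep in the laminar regime (Re ~ 0.01 at the highest
    observed blood velocities), which is what licenses the linear resistor
    representation of each channel.
    """
    if not (math.isfinite(hydraulic_diameter_m) and hydraulic_diameter_m > 0):
        raise ValueError("hydraulic diameter must be > 0")
    return fluid.density_kg_m3 * fluid.velocity_m_s * hydraulic_diameter_m / fluid.viscosity_pa_s
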