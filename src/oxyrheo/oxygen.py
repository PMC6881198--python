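"""Vertical oxygen transport through the multilayer device stack.

The device is a PDMS sandwich on a glass slide: blood channel (15 um,
aqueous), a 100 um PDMS membrane, a 100 um aqueous hydration layer,
a second 100 um PDMS membrane, and the gas reservoir on top.  Oxygen
reaches the blood only by diffusing down through this stack, so the
response time of the blood-channel oxygen tension to a gas switch is set
by the stack's diffusive timescale.

This module solves the 1-D piecewise-constant-diffusivity problem

    dc/dt = d/dz ( D(z) dc/dz ),   0 < z < L

with a no-flux bottom boundary (the glass slide) and a Dirichlet top
boundary following the gas protocol.  Concentration is carried in
mm Hg of oxygen partial pressure; with no solubility partitioning
between layers this is just a unit relabelling of concentration.

The default integrator is backward Euler on a uniform grid with
harmonic-mean interface diffusivities.  That scheme is unconditionally
stable, strictly monotone (an M-matrix), and exactly conservative when
both boundaries are no-flux, which the test suite exploits as a solver
self-check.  An explicit scheme is provided for cross-validation; it
refuses to run when the CFL-like stability bound D*dt/dz^2 <= 1/2 is
violated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "DiffusionLayer",
    "LayerStack",
    "GasProtocol",
    "CalibrationPair",
    "SternVolmerCalibration",
    "DiffusionResult",
    "default_stack",
    "simulate_gas_switch",
    "time_to_anoxia",
    "stern_volmer_calibrate",
    "linear_calibrate",
    "NOT_REACHED",
]

# Diffusion coefficients, cm^2/s: PDMS and water values used for the stack.
D_PDMS_CM2_S = 3.3e-5
D_WATER_CM2_S = 4.0e-5

NOT_REACHED = math.inf
"""Sentinel returned by :func:`time_to_anoxia` when the threshold is never crossed."""

MaterialTag = Literal["pdms", "water", "glass"]
SchemeTag = Literal["implicit", "explicit"]


@dataclass(frozen=True)
class DiffusionLayer:
    """One horizontal layer of the stack (glass is a boundary, not a layer)."""

    name: str
    thickness_m: float
    d_cm2_s: float
    material: MaterialTag

    def __post_init__(self) -> None:
        if not (math.isfinite(self.thickness_m) and self.thickness_m > 0):
            raise ValueError(f"layer {self.name!r}: thickness must be > 0")
        if not (math.isfinite(self.d_cm2_s) and self.d_cm2_s >= 0):
            raise ValueError(f"layer {self.name!r}: diffusion coefficient must be >= 0")
        if self.material == "glass":
            raise ValueError("glass is modeled as the no-flux bottom boundary, not a layer")

    @property
    def d_m2_s(self) -> float:
        return self.d_cm2_s * 1e-4


@dataclass(frozen=True)
class LayerStack:
    """Ordered layers from the glass slide (bottom, z=0) up to the gas boundary."""

    layers: Tuple[DiffusionLayer, ...]

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("stack needs at least one layer")

    @property
    def total_thickness_m(self) -> float:
        return sum(l.thickness_m for l in self.layers)

    def diffusivity_profile(self, z: np.ndarray) -> np.ndarray:
        """D(z) in m^2/s at the given heights (bottom of stack = 0)."""
        d = np.empty_like(z, dtype=float)
        bounds = np.cumsum([l.thickness_m for l in self.layers])
        idx = np.searchsorted(bounds, z, side="left")
        idx = np.clip(idx, 0, len(self.layers) - 1)
        ds = np.array([l.d_m2_s for l in self.layers])
        d[:] = ds[idx]
        return d

    def layer_midpoint(self, name: str) -> float:
        """z at the middle of the named layer; the default probe location."""
        z0 = 0.0
        for l in self.layers:
            if l.name == name:
                return z0 + 0.5 * l.thickness_m
            z0 += l.thickness_m
        raise KeyError(f"no layer named {name!r}")


def default_stack() -> LayerStack:
    """The device stack: blood 15 um, membrane 100 um, hydration 100 um, membrane 100 um."""
    return LayerStack(
        layers=(
            DiffusionLayer("blood", 15e-6, D_WATER_CM2_S, "water"),
            DiffusionLayer("membrane_lower", 100e-6, D_PDMS_CM2_S, "pdms"),
            DiffusionLayer("hydration", 100e-6, D_WATER_CM2_S, "water"),
            DiffusionLayer("membrane_upper", 100e-6, D_PDMS_CM2_S, "pdms"),
        )
    )


@dataclass(frozen=True)
class GasProtocol:
    """Piecewise-constant gas-reservoir oxygen tension: (time_s, po2_mmhg) switch events.

    The first event fixes the tension from its time onward; the default cycle
    alternates 160 <-> 0 mm Hg.
    """

    events: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.events) == 0:
            raise ValueError("protocol needs at least one event")
        times = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        for _, po2 in self.events:
            if not (0.0 <= po2 <= 160.0):
                raise ValueError(f"gas tension must lie in [0, 160] mm Hg, got {po2}")

    @classmethod
    def cycle(
        cls, period_s: float, n_cycles: int, high_mmhg: float = 160.0, low_mmhg: float = 0.0
    ) -> "GasProtocol":
        """Square-wave cycling starting high at t=0: high/low half-periods."""
        events = []
        for i in range(n_cycles):
            events.append((i * period_s, high_mmhg))
            events.append((i * period_s + 0.5 * period_s, low_mmhg))
        return cls(events=tuple(events))

    @classmethod
    def step_down(cls, t_switch_s: float = 0.0, high_mmhg: float = 160.0) -> "GasProtocol":
        """Single 160 -> 0 mm Hg switch at t_switch_s (high before the switch)."""
        if t_switch_s > 0:
            return cls(events=((0.0, high_mmhg), (t_switch_s, 0.0)))
        return cls(events=((0.0, 0.0),))

    def tension_at(self, t: float) -> float:
        po2 = self.events[0][1]
        for et, ep in self.events:
            if t >= et:
                po2 = ep
            else:
                break
        return po2


@dataclass(frozen=True)
class DiffusionResult:
    """Space-time oxygen field from :func:`simulate_gas_switch`."""

    z_m: np.ndarray
    t_s: np.ndarray
    c_mmhg: np.ndarray  # shape (n_times, n_nodes)
    stack: LayerStack

    def probe(self, z_probe_m: float) -> np.ndarray:
        """Time series at the node nearest z_probe_m."""
        i = int(np.argmin(np.abs(self.z_m - z_probe_m)))
        return self.c_mmhg[:, i]

    def profile_at(self, t: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.t_s - t)))
        return self.c_mmhg[i]


def _interface_diffusivities(d_nodes: np.ndarray) -> np.ndarray:
    """Harmonic-mean diffusivity at cell interfaces (flux continuity)."""
    a, b = d_nodes[:-1], d_nodes[1:]
    out = np.zeros_like(a)
    nz = (a > 0) & (b > 0)
    out[nz] = 2.0 * a[nz] * b[nz] / (a[nz] + b[nz])
    return out


def simulate_gas_switch(
    stack: LayerStack,
    protocol: GasProtocol,
    dz_m: float = 1e-6,
    dt_s: float = 0.05,
    t_end_s: float = 120.0,
    initial_mmhg: float = 160.0,
    scheme: SchemeTag = "implicit",
    bottom: Literal["no_flux", "dirichlet"] = "no_flux",
    top: Literal["dirichlet", "no_flux"] = "dirichlet",
    store_every: int = 1,
) -> DiffusionResult:
    """Integrate the 1-D layer-stack diffusion problem through the gas protocol.

    Parameters
    ----------
    stack
        Layer stack, glass at the bottom.
    protocol
        Gas-reservoir tension applied as the top Dirichlet value.
    dz_m, dt_s
        Uniform grid spacing and time step.  The grid must resolve the
        thinnest layer with at least 5 nodes.
    t_end_s
        End of the integration window.
    initial_mmhg
        Uniform initial oxygen tension.
    scheme
        "implicit" (backward Euler, unconditionally stable; default) or
        "explicit" (forward Euler; raises before integrating if the
        stability bound D*dt/dz^2 <= 0.5 is violated).
    bottom
        "no_flux" models the glass slide; "dirichlet" clamps the bottom node
        at the protocol tension too (used only for self-tests).
    top
        "dirichlet" (the gas reservoir; default) or "no_flux", which seals
        the stack: with both boundaries no-flux the discrete scheme conserves
        the integrated concentration exactly, a solver self-test mode.
    store_every
        Keep every k-th time level in the result.

    Returns
    -------
    DiffusionResult
        Field c(z, t) in mm Hg on node centers z in [dz/2, L - dz/2], plus
        the top boundary value appended as the last node.
    """
    thinnest = min(l.thickness_m for l in stack.layers)
    if thinnest / dz_m < 5:
        raise ValueError(
            f"grid spacing {dz_m} m does not resolve the thinnest layer "
            f"({thinnest} m) with >= 5 nodes"
        )
    if dt_s <= 0 or t_end_s <= 0:
        raise ValueError("dt and t_end must be > 0")

    length = stack.total_thickness_m
    n = int(round(length / dz_m))
    # finite-volume cell centers
    z = (np.arange(n) + 0.5) * (length / n)
    dz = length / n
    d_nodes = stack.diffusivity_profile(z)
    d_iface = _interface_diffusivities(d_nodes)  # n-1 interior interfaces
    # top boundary face couples the last cell to the Dirichlet gas value at
    # distance dz/2; use the last cell's diffusivity there.
    d_top = d_nodes[-1]

    if scheme == "explicit":
        r_max = float(np.max(d_nodes)) * dt_s / dz**2
        if r_max > 0.5:
            raise ValueError(
                f"explicit scheme unstable: D*dt/dz^2 = {r_max:.3g} > 0.5; "
                "reduce dt or use the implicit scheme"
            )

    # Assemble the flux-conservative Laplacian L (rows sum appropriately):
    # dc_i/dt = [F_{i+1/2} - F_{i-1/2}] / dz,  F = D dc/dz.
    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    for i in range(n):
        dl = d_iface[i - 1] if i > 0 else 0.0  # bottom face: no flux
        du = d_iface[i] if i < n - 1 else 0.0
        lower[i] = dl / dz**2
        upper[i] = du / dz**2
        diag[i] = -(dl + du) / dz**2
    # top cell exchanges with the gas boundary at distance dz/2 -> coefficient 2*D/dz^2
    top_coeff = 2.0 * d_top / dz**2 if top == "dirichlet" else 0.0
    diag[-1] -= top_coeff

    n_steps = int(math.ceil(t_end_s / dt_s))
    times = [0.0]
    c = np.full(n, float(initial_mmhg))
    if bottom == "dirichlet":
        c[0] = protocol.tension_at(0.0)
    frames = [c.copy()]

    if scheme == "implicit":
        # banded matrix for (I - dt*L)
        ab = np.zeros((3, n))
        ab[0, 1:] = -dt_s * upper[:-1]
        ab[1, :] = 1.0 - dt_s * diag
        ab[2, :-1] = -dt_s * lower[1:]

    for k in range(1, n_steps + 1):
        t_new = k * dt_s
        g = protocol.tension_at(t_new)
        if scheme == "implicit":
            rhs = c.copy()
            rhs[-1] += dt_s * top_coeff * g
            if bottom == "dirichlet":
                # clamp bottom node: identity row
                ab_b = ab.copy()
                ab_b[1, 0] = 1.0
                ab_b[0, 1] = 0.0
                rhs[0] = g
                c = solve_banded((1, 1), ab_b, rhs)
            else:
                c = solve_banded((1, 1), ab, rhs)
        else:
            g_prev = protocol.tension_at((k - 1) * dt_s)
            flux = np.zeros(n)
            flux += diag * c
            flux[:-1] += upper[:-1] * c[1:]
            flux[1:] += lower[1:] * c[:-1]
            flux[-1] += top_coeff * g_prev
            c = c + dt_s * flux
            if bottom == "dirichlet":
                c[0] = g
        if k % store_every == 0 or k == n_steps:
            times.append(t_new)
            frames.append(c.copy())

    c_arr = np.vstack(frames)
    if top == "dirichlet":
        # append the boundary value as a pseudo-node at z = L for plotting/tests
        z = np.concatenate([z, [length]])
        g_col = np.array([[protocol.tension_at(t)] for t in times])
        c_arr = np.hstack([c_arr, g_col])
    return DiffusionResult(z_m=z, t_s=np.asarray(times), c_mmhg=c_arr, stack=stack)


def time_to_anoxia(
    result: DiffusionResult,
    probe_z_m: Optional[float] = None,
    threshold_mmhg: float = 2.0,
    after_s: float = 0.0,
) -> float:
    """First time the blood-channel probe falls below the threshold.

    The paper-facing operational definition of "reached 0 mm Hg": the probe
    (default: blood-layer midpoint) crossing 2 mm Hg, i.e. 1.25% of ambient.
    Linear interpolation between stored time levels; returns ``NOT_REACHED``
    (inf) if the threshold is never crossed in the simulated span.
    """
    if threshold_mmhg <= 0:
        raise ValueError("threshold must be > 0")
    if probe_z_m is None:
        probe_z_m = result.stack.layer_midpoint("blood")
    series = result.probe(probe_z_m)
    t = result.t_s
    mask = t >= after_s
    series, t = series[mask], t[mask]
    below = series < threshold_mmhg
    if not np.any(below):
        return NOT_REACHED
    i = int(np.argmax(below))
    if i == 0:
        return float(t[0])
    c0, c1 = series[i - 1], series[i]
    t0, t1 = t[i - 1], t[i]
    frac = (c0 - threshold_mmhg) / (c0 - c1)
    return float(t0 + frac * (t1 - t0))


@dataclass(frozen=True)
class CalibrationPair:
    """Two-point luminescence calibration: dye intensity at 0 and 160 mm Hg.

    Oxygen quenches Ru(bpy)3 luminescence, so the anoxic intensity is the
    brighter of the two.
    """

    i0: float
    i160: float

    def __post_init__(self) -> None:
        if not (self.i0 > self.i160 > 0):
            raise ValueError(
                f"calibration requires I0 > I160 > 0 (oxygen quenches), got I0={self.i0}, I160={self.i160}"
            )


@dataclass(frozen=True)
class SternVolmerCalibration:
    """I0/I = 1 + K_sv * pO2 with K_sv from the two calibration points."""

    i0: float
    k_sv_per_mmhg: float

    def intensity_to_po2(self, intensity: float) -> float:
        if intensity <= 0:
            raise ValueError("intensity must be > 0")
        if intensity >= self.i0:
            # brighter than the anoxic reference: clamp (measurement noise)
            return 0.0
        return (self.i0 / intensity - 1.0) / self.k_sv_per_mmhg


def stern_volmer_calibrate(pair: CalibrationPair) -> SternVolmerCalibration:
    """Quenching constant from the two-point calibration: K_sv = (I0/I160 - 1)/160."""
    k_sv = (pair.i0 / pair.i160 - 1.0) / 160.0
    return SternVolmerCalibration(i0=pair.i0, k_sv_per_mmhg=k_sv)


@dataclass(frozen=True)
class LinearCalibration:
    """Linear two-point alternative: pO2 = 160 * (I0 - I)/(I0 - I160), clamped at 0."""

    i0: float
    i160: float

    def intensity_to_po2(self, intensity: float) -> float:
        if intensity <= 0:
            raise ValueError("intensity must be > 0")
        if intensity >= self.i0:
            return 0.0
        return 160.0 * (self.i0 - intensity) / (self.i0 - self.i160)


def linear_calibrate(pair: CalibrationPair) -> LinearCalibration:
    """Linear interpolation between the calibration endpoints.

    Stern–Volmer is the physically grounded default for a collisionally
    quenched dye; this is provided for sensitivity checks.
    """
    return LinearCalibration(i0=pair.i0, i160=pair.i160)
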