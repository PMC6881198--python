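"""Rheogram inference: pressure-step velocity data -> effective viscosity curves.

The measurement is indirect.  At each applied driving pressure the device
records the maximum midline velocity in the experimental channel; what we
want is the effective viscosity of the blood in that channel at the
corresponding average shear rate.  The link is the hydraulic circuit:

    dp_total = Q_total * R_hyd(eta1, eta2, eta3)

with section viscosities eta1 (inlet dissipater), eta2 (bypass) and eta3
(experimental).  Writing eta1 = A*eta3 and eta2 = B*eta3 reduces the
circuit to a single unknown, inverted in closed form:

    eta3 = (dp/Q_total) * S / (1 + c1*A*S),   S = 1/(c2*B) + 1/c3

For a shear-thinning fluid A and B are not 1: different sections run at
different shear rates, hence different effective viscosities.  They are
determined self-consistently by a fixed point: invert with the current
(A, B), fit a provisional power law eta = K*gdot**(n-1) across the curve,
update A = (g1/g3)**(n-1), B = (g2/g3)**(n-1) from the section shear
rates, and repeat until the viscosities stop moving.

Section shear rates follow a configurable velocity-allocation rule.  The
default ("continuity") derives section mean velocities from flow
continuity — the inlet carries Q_total, the branches split so both see
the same pressure drop — which conserves mass.  The alternative
("area_proportional") sets section velocities proportional to channel
cross-sectional area, the linearization used in the original analysis;
the two disagree, and the discrepancy is logged when both are available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .device import ChannelGeometry, DeviceNetwork, network_resistance

__all__ = [
    "RheologyTrace",
    "OperatingPoint",
    "ViscosityRatioFactors",
    "RheogramPoint",
    "Rheogram",
    "InversionSettings",
    "ConvergenceError",
    "average_shear_rate",
    "experimental_flow_from_velocity",
    "total_flow",
    "viscosity_eq7",
    "infer_rheogram",
]

logger = logging.getLogger(__name__)

#: laminar square-duct ratio of mean to maximum (midline) velocity
SQUARE_DUCT_PROFILE_FACTOR = 0.477

TRACE_COLUMNS = ("time_s", "pressure_pa", "po2_mmhg", "umax_um_s", "replicate")


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed; carries the last iterate for diagnosis."""

    def __init__(self, message: str, last_rheogram: Optional["Rheogram"] = None):
        super().__init__(message)
        self.last_rheogram = last_rheogram


@dataclass(frozen=True)
class RheologyTrace:
    """Raw measured (or synthetic) velocity trace for one sample.

    ``records`` is a DataFrame with columns time_s, pressure_pa, po2_mmhg,
    umax_um_s, replicate.  Each (pressure, oxygen) step must carry at least
    one replicate.
    """

    records: pd.DataFrame
    sample_id: str = "sample"
    device: Optional[str] = None

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trace is missing required columns: {missing}")
        if len(df) == 0:
            raise ValueError("trace has no records")
        if (df["pressure_pa"] <= 0).any():
            raise ValueError("driving pressures must be > 0")
        if (df["umax_um_s"] < 0).any():
            raise ValueError("velocities must be >= 0")

    def oxygen_tensions(self) -> List[float]:
        return sorted(self.records["po2_mmhg"].unique())

    def steps(self, po2_mmhg: float) -> pd.DataFrame:
        return self.records[self.records["po2_mmhg"] == po2_mmhg]


@dataclass(frozen=True)
class ViscosityRatioFactors:
    """Per-step viscosity ratios A = eta1/eta3, B = eta2/eta3 (1 for a Newtonian fluid)."""

    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("viscosity ratio factors must be > 0")


@dataclass(frozen=True)
class OperatingPoint:
    """One inverted pressure step."""

    dp_total_pa: float
    q_total_m3_s: float
    q_experimental_m3_s: float
    shear_rate_per_s: float
    po2_mmhg: float

    def __post_init__(self) -> None:
        if self.dp_total_pa <= 0:
            raise ValueError("total pressure drop must be > 0")
        if self.q_experimental_m3_s > self.q_total_m3_s * (1 + 1e-12):
            raise ValueError("experimental flow cannot exceed total flow")


@dataclass(frozen=True)
class RheogramPoint:
    shear_rate_per_s: float
    viscosity_pa_s: float
    shear_stress_pa: float
    po2_mmhg: float
    sd_pa_s: float = 0.0


@dataclass(frozen=True)
class Rheogram:
    """Effective viscosity vs average shear rate at one oxygen tension."""

    points: Tuple[RheogramPoint, ...]
    po2_mmhg: float
    sample_id: str = "sample"
    converged: bool = True
    iterations: int = 0

    def __post_init__(self) -> None:
        g = [p.shear_rate_per_s for p in self.points]
        if any(b <= a for a, b in zip(g, g[1:])):
            raise ValueError("shear rates must be strictly increasing within a rheogram")
        for p in self.points:
            if p.viscosity_pa_s <= 0:
                raise ValueError("viscosities must be > 0")
            if abs(p.shear_stress_pa - p.viscosity_pa_s * p.shear_rate_per_s) > 1e-12 * max(
                p.shear_stress_pa, 1e-300
            ):
                raise ValueError("shear stress inconsistent with viscosity * shear rate")

    @property
    def shear_rates(self) -> np.ndarray:
        return np.array([p.shear_rate_per_s for p in self.points])

    @property
    def viscosities(self) -> np.ndarray:
        return np.array([p.viscosity_pa_s for p in self.points])

    @property
    def stresses(self) -> np.ndarray:
        return np.array([p.shear_stress_pa for p in self.points])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "po2_mmhg": [p.po2_mmhg for p in self.points],
                "shear_rate_per_s": [p.shear_rate_per_s for p in self.points],
                "viscosity_pa_s": [p.viscosity_pa_s for p in self.points],
                "shear_stress_pa": [p.shear_stress_pa for p in self.points],
                "sd_pa_s": [p.sd_pa_s for p in self.points],
            }
        )


@dataclass(frozen=True)
class InversionSettings:
    """Numerical settings for the fixed-point rheogram inversion."""

    profile_factor: float = SQUARE_DUCT_PROFILE_FACTOR
    velocity_rule: Literal["continuity", "area_proportional"] = "continuity"
    tol: float = 1e-8
    max_iter: int = 100
    damping: float = 0.5
    steady_state_fraction: float = 0.5
    min_steps: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.profile_factor <= 1):
            raise ValueError("profile factor must lie in (0, 1]")
        if not (0 <= self.steady_state_fraction <= 1):
            raise ValueError("steady-state fraction must lie in [0, 1]")


def average_shear_rate(max_velocity_um_s: float, half_width_um: float) -> float:
    """Average shear rate = maximum midline velocity / channel half-width.

    With the 15 um experimental channel this is u_max / 7.5 um, the
    device's operational shear-rate definition.
    """
    if half_width_um <= 0:
        raise ValueError("half-width must be > 0")
    if max_velocity_um_s < 0:
        raise ValueError("velocity must be >= 0")
    return max_velocity_um_s / half_width_um


def experimental_flow_from_velocity(
    max_velocity_m_s: float, geometry: ChannelGeometry, profile_factor: float = SQUARE_DUCT_PROFILE_FACTOR
) -> float:
    """Volumetric flow from the midline maximum velocity: Q = f * u_max * h * w.

    ``profile_factor`` is the mean-to-maximum velocity ratio of the laminar
    duct profile (0.477 for a square duct; 1 would be plug flow).
    """
    if not (0 < profile_factor <= 1):
        raise ValueError("profile factor must lie in (0, 1]")
    if max_velocity_m_s < 0:
        raise ValueError("velocity must be >= 0")
    return profile_factor * max_velocity_m_s * geometry.area_m2


def total_flow(
    q_experimental_m3_s: float, network: DeviceNetwork, factors: ViscosityRatioFactors
) -> float:
    """Total device flow from the experimental-branch flow.

    The parallel branches see the same pressure drop, so
    Q2/Q3 = (c3*eta3)/(c2*eta2) = c3/(c2*B) and
    Q_total = Q3 * (1 + c3/(c2*B)).
    """
    if q_experimental_m3_s < 0:
        raise ValueError("flow must be >= 0")
    return q_experimental_m3_s * (1.0 + network.c3 / (network.c2 * factors.b))


def viscosity_eq7(
    dp_total_pa: float,
    q_total_m3_s: float,
    network: DeviceNetwork,
    factors: ViscosityRatioFactors,
) -> float:
    """Closed-form experimental-zone viscosity from one operating point.

    eta3 = (dp/Q) * S / (1 + c1*A*S) with S = 1/(c2*B) + 1/c3.  This is the
    algebraic inverse of the forward circuit equation for fixed ratios A, B;
    with A = B = 1 it recovers a Newtonian fluid's viscosity exactly.
    """
    if dp_total_pa <= 0 or q_total_m3_s <= 0:
        raise ValueError("pressure drop and total flow must be > 0")
    s = 1.0 / (network.c2 * factors.b) + 1.0 / network.c3
    denom = 1.0 + network.c1 * factors.a * s
    eta3 = (dp_total_pa / q_total_m3_s) * s / denom
    if not (math.isfinite(eta3) and eta3 > 0):
        raise ValueError(f"degenerate circuit constants produced eta3={eta3!r}")
    return eta3


def section_shear_rates(
    network: DeviceNetwork,
    q_total_m3_s: float,
    q_experimental_m3_s: float,
    umax_experimental_m_s: float,
    settings: InversionSettings,
) -> Tuple[float, float, float]:
    """Characteristic shear rates (g1, g2, g3) of the three sections.

    continuity rule
        The inlet carries Q_total and each branch its continuity share;
        section midline velocity u_i = Q_i / (f * A_i) and g_i = u_i / (h_i/2).
    area_proportional rule
        Section velocities proportional to cross-sectional area
        (u_i = u3 * A_i / A3), the original linearization.
    """
    geos = {
        "inlet": network.inlet_resistor.geometry,
        "bypass": network.bypass.geometry,
        "experimental": network.experimental.geometry,
    }
    if any(g is None for g in geos.values()):
        raise ValueError(
            "section shear-rate allocation requires geometries on all three resistors"
        )
    g_exp = geos["experimental"]
    g3 = umax_experimental_m_s / g_exp.half_height_m
    if settings.velocity_rule == "continuity":
        f = settings.profile_factor
        u1 = q_total_m3_s / (f * geos["inlet"].area_m2)
        u2 = (q_total_m3_s - q_experimental_m3_s) / (f * geos["bypass"].area_m2)
        g1 = u1 / geos["inlet"].half_height_m
        g2 = u2 / geos["bypass"].half_height_m
    elif settings.velocity_rule == "area_proportional":
        u3 = umax_experimental_m_s
        u1 = u3 * geos["inlet"].area_m2 / g_exp.area_m2
        u2 = u3 * geos["bypass"].area_m2 / g_exp.area_m2
        g1 = u1 / geos["inlet"].half_height_m
        g2 = u2 / geos["bypass"].half_height_m
    else:  # pragma: no cover - guarded by InversionSettings type
        raise ValueError(f"unknown velocity rule {settings.velocity_rule!r}")
    return g1, g2, g3


def _steady_state_window(group: pd.DataFrame, fraction: float) -> pd.DataFrame:
    """Keep records from the trailing `fraction` of each step's observed span."""
    if fraction >= 1.0 or len(group) == 1:
        return group
    t0, t1 = group["time_s"].min(), group["time_s"].max()
    if t1 == t0:
        return group
    cutoff = t0 + (1.0 - fraction) * (t1 - t0)
    kept = group[group["time_s"] >= cutoff]
    return kept if len(kept) else group


def _aggregate_steps(
    trace: RheologyTrace, po2: float, settings: InversionSettings
) -> pd.DataFrame:
    """Mean and SD of u_max per pressure step after steady-state windowing."""
    rows = []
    for pressure, grp in trace.steps(po2).groupby("pressure_pa"):
        kept = _steady_state_window(grp, settings.steady_state_fraction)
        u = kept["umax_um_s"].to_numpy(dtype=float)
        rows.append(
            {
                "pressure_pa": float(pressure),
                "umax_um_s": float(np.mean(u)),
                "umax_sd_um_s": float(np.std(u, ddof=1)) if len(u) > 1 else 0.0,
                "n_replicates": int(len(u)),
            }
        )
    df = pd.DataFrame(rows).sort_values("pressure_pa").reset_index(drop=True)
    return df


def _fit_provisional_n(shear_rates: np.ndarray, viscosities: np.ndarray) -> float:
    """Slope of log tau on log gdot across the provisional curve."""
    x = np.log10(shear_rates)
    y = np.log10(viscosities * shear_rates)
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def infer_rheogram(
    trace: RheologyTrace,
    network: DeviceNetwork,
    settings: InversionSettings = InversionSettings(),
) -> Dict[float, Rheogram]:
    """Invert a pressure-step trace into one rheogram per oxygen tension.

    Procedure per oxygen tension: average replicates within the steady-state
    window of each pressure step; initialize A = B = 1; repeatedly (i) convert
    velocity to experimental and total flow, (ii) invert the circuit for eta3
    at every step, (iii) fit a provisional power law across the curve,
    (iv) update per-step A, B from the section shear rates, until the maximum
    relative change in eta3 drops below ``settings.tol``.  Oscillation
    triggers damped updates.

    Replicate scatter is propagated to the rheogram through the first-order
    sensitivity of the closed-form inversion, which at fixed (A, B) is
    d(eta3)/eta3 = -d(u)/u.

    Returns a dict keyed by oxygen tension.  Raises ``ConvergenceError``
    (carrying the last iterate) on non-convergence and ``ValueError`` for
    degenerate input (all-zero velocities, fewer than ``min_steps`` steps).
    """
    geo_exp = network.experimental.geometry
    if geo_exp is None:
        raise ValueError("experimental resistor needs a geometry to convert velocity to flow")
    can_allocate = network.has_geometries()
    if not can_allocate:
        logger.warning(
            "resistor geometries missing: section shear rates unavailable, using A=B=1 "
            "(Newtonian allocation)"
        )

    out: Dict[float, Rheogram] = {}
    half_width_um = geo_exp.half_height_m * 1e6
    for po2 in trace.oxygen_tensions():
        steps = _aggregate_steps(trace, po2, settings)
        if len(steps) < settings.min_steps:
            raise ValueError(
                f"need at least {settings.min_steps} pressure steps at {po2} mm Hg, got {len(steps)}"
            )
        if (steps["umax_um_s"] <= 0).all():
            raise ValueError(f"all velocities are zero at {po2} mm Hg; nothing to invert")
        if (steps["umax_um_s"] <= 0).any():
            bad = steps[steps["umax_um_s"] <= 0]
            raise ValueError(
                f"zero mean velocity at pressures {bad['pressure_pa'].tolist()} ({po2} mm Hg)"
            )

        dp = steps["pressure_pa"].to_numpy(dtype=float)
        umax_m_s = steps["umax_um_s"].to_numpy(dtype=float) * 1e-6
        rel_sd = np.where(
            steps["umax_um_s"] > 0,
            steps["umax_sd_um_s"].to_numpy(dtype=float) / steps["umax_um_s"].to_numpy(dtype=float),
            0.0,
        )
        gdot3 = steps["umax_um_s"].to_numpy(dtype=float) / half_width_um
        q_exp = np.array(
            [
                experimental_flow_from_velocity(u, geo_exp, settings.profile_factor)
                for u in umax_m_s
            ]
        )

        m = len(steps)
        a = np.ones(m)
        b = np.ones(m)
        eta3 = None
        prev_delta = None
        converged = False
        iterations = 0
        for it in range(1, settings.max_iter + 1):
            iterations = it
            factors = [ViscosityRatioFactors(a=a[i], b=b[i]) for i in range(m)]
            q_tot = np.array([total_flow(q_exp[i], network, factors[i]) for i in range(m)])
            eta3_new = np.array(
                [viscosity_eq7(dp[i], q_tot[i], network, factors[i]) for i in range(m)]
            )
            if eta3 is not None:
                delta = float(np.max(np.abs(eta3_new - eta3) / eta3))
                if delta < settings.tol:
                    eta3 = eta3_new
                    converged = True
                    break
                if prev_delta is not None and delta > prev_delta:
                    # oscillation: damp the viscosity update
                    eta3_new = eta3 + settings.damping * (eta3_new - eta3)
                prev_delta = delta
            eta3 = eta3_new

            if can_allocate and m >= 2:
                n_prov = _fit_provisional_n(gdot3, eta3)
                a_new = np.empty(m)
                b_new = np.empty(m)
                for i in range(m):
                    g1, g2, g3 = section_shear_rates(
                        network, q_tot[i], q_exp[i], umax_m_s[i], settings
                    )
                    a_new[i] = (g1 / g3) ** (n_prov - 1.0)
                    b_new[i] = (g2 / g3) ** (n_prov - 1.0)
                a, b = a_new, b_new
            else:
                converged = True
                break

        order = np.argsort(gdot3)
        points = tuple(
            RheogramPoint(
                shear_rate_per_s=float(gdot3[i]),
                viscosity_pa_s=float(eta3[i]),
                shear_stress_pa=float(eta3[i] * gdot3[i]),
                po2_mmhg=float(po2),
                sd_pa_s=float(eta3[i] * rel_sd[i]),
            )
            for i in order
        )
        rheo = Rheogram(
            points=points,
            po2_mmhg=float(po2),
            sample_id=trace.sample_id,
            converged=converged,
            iterations=iterations,
        )
        if not converged:
            raise ConvergenceError(
                f"rheogram inversion did not converge in {settings.max_iter} iterations "
                f"at {po2} mm Hg",
                last_rheogram=rheo,
            )
        out[float(po2)] = rheo
    return out
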