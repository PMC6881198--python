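"""Power-law rheology fits and the fractional-velocity-change metric.

Blood is shear thinning: its effective viscosity decreases with shear
rate.  Over the shear-rate decade probed by the device this is well
captured by the Ostwald–de Waele power law

    tau = K * gammadot**n

with flow behavior index n (n = 1 Newtonian, n < 1 shear thinning) and
consistency index K (Pa s^n).  n is estimated as the slope of the
ordinary least-squares line of log10(tau) on log10(gammadot); the
R-squared of that linear fit is the reported goodness of fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _st

__all__ = ["PowerLawFit", "fit_power_law", "shear_stress", "fractional_velocity_change"]


@dataclass(frozen=True)
class PowerLawFit:
    """Result of a log-log power-law fit tau = K * gammadot**n."""

    n: float
    """Flow behavior index (slope in log-log space)."""
    k_pa_sn: float
    """Consistency index K (Pa s^n); 10**intercept of the log10 fit."""
    r2: float
    """R-squared of the linear fit in log-log space (<= 1)."""
    n_points: int
    po2_mmhg: Optional[float] = None

    def viscosity(self, shear_rate_per_s: float) -> float:
        """Fitted effective viscosity eta = K * gammadot**(n-1)."""
        return self.k_pa_sn * shear_rate_per_s ** (self.n - 1.0)

    def to_dict(self) -> dict:
        return {
            "po2_mmhg": self.po2_mmhg,
            "n": self.n,
            "K_pa_sn": self.k_pa_sn,
            "r2": self.r2,
            "n_points": self.n_points,
        }


def fit_power_law(
    shear_rates_per_s: Sequence[float],
    shear_stresses_pa: Sequence[float],
    po2_mmhg: Optional[float] = None,
    weights: Optional[Sequence[float]] = None,
) -> PowerLawFit:
    """Fit tau = K * gammadot**n by least squares of log10 tau on log10 gammadot.

    Parameters
    ----------
    shear_rates_per_s, shear_stresses_pa
        Paired observations; all strictly positive, at least 3 points.
    po2_mmhg
        Oxygen-tension label carried through to the fit record.
    weights
        Optional per-point weights for a weighted fit (e.g. inverse variance
        from replicate SDs).  Default is the unweighted fit.

    Returns
    -------
    PowerLawFit
        n (slope), K (10**intercept), and the R-squared of the linear fit.
    """
    g = np.asarray(shear_rates_per_s, dtype=float)
    t = np.asarray(shear_stresses_pa, dtype=float)
    if g.shape != t.shape or g.ndim != 1:
        raise ValueError("shear rates and stresses must be 1-D arrays of equal length")
    if g.size < 3:
        raise ValueError(f"power-law fit needs at least 3 points, got {g.size}")
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(t))):
        raise ValueError("non-finite values in fit input")
    if np.any(g <= 0) or np.any(t <= 0):
        raise ValueError("power-law fit requires strictly positive shear rates and stresses")

    x = np.log10(g)
    y = np.log10(t)
    if weights is None:
        res = _st.linregress(x, y)
        slope, intercept, r = res.slope, res.intercept, res.rvalue
        r2 = r * r
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative with at least one positive entry")
        coef, _ = np.polyfit(x, y, 1, w=np.sqrt(w), cov=True)
        slope, intercept = float(coef[0]), float(coef[1])
        yhat = slope * x + intercept
        ybar = np.average(y, weights=w)
        ss_res = float(np.sum(w * (y - yhat) ** 2))
        ss_tot = float(np.sum(w * (y - ybar) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    if slope <= 0:
        raise ValueError(f"fitted flow behavior index must be > 0, got {slope}")
    return PowerLawFit(
        n=float(slope),
        k_pa_sn=float(10.0**intercept),
        r2=float(min(r2, 1.0)),
        n_points=int(g.size),
        po2_mmhg=po2_mmhg,
    )


def shear_stress(viscosity_pa_s: float, shear_rate_per_s: float) -> float:
    """tau = eta * gammadot, linking the viscosity rheogram to the stress curve."""
    if viscosity_pa_s < 0 or shear_rate_per_s < 0:
        raise ValueError("viscosity and shear rate must be >= 0")
    return viscosity_pa_s * shear_rate_per_s


def fractional_velocity_change(v_oxygenated: float, v_deoxygenated: float) -> float:
    """Per-sample hypoxia response metric (v_ox - v_deox) / v_ox.

    0 for oxygen-independent flow (healthy blood); approaches 1 as
    deoxygenated flow stops (full occlusion).
    """
    if not (math.isfinite(v_oxygenated) and v_oxygenated > 0):
        raise ValueError(f"oxygenated velocity must be > 0, got {v_oxygenated!r}")
    if not math.isfinite(v_deoxygenated) or v_deoxygenated < 0:
        raise ValueError(f"deoxygenated velocity must be >= 0, got {v_deoxygenated!r}")
    return (v_oxygenated - v_deoxygenated) / v_oxygenated
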