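"""Synthetic blood samples, traces, and cohorts for pipeline testing.

No patient measurements ship with this package, so every pipeline stage
is exercised against a generator that reproduces the statistical
structure of the real experiment:

* an oxygen- and HbS-dependent power-law material law.  For untransfused
  sickle blood the flow behavior index interpolates through the anchor
  points (92 mm Hg, 0.76), (46, 0.74), (0, 0.87) — the cohort means of
  the measured data — and the consistency index rises as oxygen falls so
  that effective viscosity at 100/s strictly increases with
  deoxygenation.  Healthy (HbS = 0) blood is oxygen independent.
* a forward device model: at each applied pressure the nonlinear circuit
  equation (shear-dependent section viscosities) is solved for the flow
  by bracketed root finding, then converted to the midline velocity.
* replicate noise: each pressure step emits ~18 multiplicative-Gaussian
  "video capture" replicates in the steady-state window, preceded by a
  few transient captures that the inversion's windowing must discard.
* cohorts: per-patient flow-behavior-index anchors are drawn around the
  population anchors with the observed between-subject SDs.
* simulated transfusion: donor and patient blood mixed by hemoglobin
  mass balance at fixed hematocrit, with a patient-specific sensitivity
  exponent controlling how quickly the mixture's rheology recovers the
  healthy shape.

Everything is deterministic given the seed, and ground truth is always
returned alongside the synthetic data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .device import ChannelGeometry, DeviceNetwork, HydraulicResistor
from .viscometry import (
    InversionSettings,
    RheologyTrace,
    experimental_flow_from_velocity,
)

__all__ = [
    "SampleComposition",
    "BloodModel",
    "BloodModelParams",
    "CohortSpec",
    "default_network",
    "default_pressure_steps",
    "build_blood_model",
    "mix_transfusion",
    "transfusion_volume_fraction",
    "mixture_blood_model",
    "forward_operating_point",
    "generate_trace",
    "generate_cohort",
]

DEFAULT_OXYGEN_TENSIONS = (92.0, 46.0, 0.0)

#: population anchors (pO2 mm Hg -> flow behavior index) for untransfused sickle blood
DEFAULT_N_ANCHORS: Dict[float, float] = {92.0: 0.76, 46.0: 0.74, 0.0: 0.87}
#: consistency-index multipliers relative to the oxygenated K (illustrative:
#: no viscosity magnitudes are published for this assay)
DEFAULT_K_MULTIPLIERS: Dict[float, float] = {92.0: 1.0, 46.0: 1.35, 0.0: 1.9}
#: between-subject SD of the flow behavior index at each tension (cohort spread)
DEFAULT_BETWEEN_SUBJECT_SD: Dict[float, float] = {92.0: 0.075, 46.0: 0.049, 0.0: 0.056}


@dataclass(frozen=True)
class SampleComposition:
    """Hematologic composition of one prepared sample (plasma replaced, fixed HCT)."""

    hct: float = 0.25
    mchc_g_dl: float = 33.0
    hbs: float = 0.0
    hba: float = 0.0
    hbf: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.hct < 1.0):
            raise ValueError(f"HCT must lie in (0, 1), got {self.hct}")
        if self.mchc_g_dl <= 0:
            raise ValueError("MCHC must be > 0")
        for name in ("hbs", "hba", "hbf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} fraction must be >= 0")
        if self.hbs + self.hba + self.hbf > 1.0 + 1e-9:
            raise ValueError("hemoglobin fractions must sum to <= 1")

    @property
    def hb_mass_per_dl_blood(self) -> float:
        """Total hemoglobin mass per dL of blood: HCT * MCHC."""
        return self.hct * self.mchc_g_dl


def _interp_clamped(x: float, xs: np.ndarray, ys: np.ndarray) -> float:
    """Piecewise-linear interpolation, constant beyond the anchor range."""
    return float(np.interp(x, xs, ys))


@dataclass(frozen=True)
class BloodModel:
    """Oxygen-dependent power-law material law tau = K(pO2) * gdot**n(pO2).

    ``sensitivity`` governs how nonlinearly a transfusion mixture recovers
    healthy rheology; ``noise_cv`` is the multiplicative replicate noise of
    the velocity measurement.
    """

    po2_anchors: Tuple[float, ...]
    n_anchors: Tuple[float, ...]
    k_anchors_pa_sn: Tuple[float, ...]
    sensitivity: float = 1.0
    noise_cv: float = 0.05
    label: str = "blood"

    def __post_init__(self) -> None:
        po2 = np.asarray(self.po2_anchors, dtype=float)
        n = np.asarray(self.n_anchors, dtype=float)
        k = np.asarray(self.k_anchors_pa_sn, dtype=float)
        if not (po2.size == n.size == k.size and po2.size >= 1):
            raise ValueError("anchor arrays must be non-empty and of equal length")
        if np.any(np.diff(po2) <= 0):
            raise ValueError("pO2 anchors must be strictly increasing")
        if not np.all(np.isfinite(n)) or np.any(n <= 0) or np.any(n >= 1.5):
            raise ValueError("flow behavior anchors must be finite and in (0, 1.5)")
        if not np.all(np.isfinite(k)) or np.any(k <= 0):
            raise ValueError("consistency anchors must be finite and > 0")
        if self.sensitivity < 0:
            raise ValueError("sensitivity must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")

    def n_at(self, po2_mmhg: float) -> float:
        return _interp_clamped(
            po2_mmhg, np.asarray(self.po2_anchors), np.asarray(self.n_anchors)
        )

    def k_at(self, po2_mmhg: float) -> float:
        # interpolate log K so multiplicative anchors mix geometrically
        logk = _interp_clamped(
            po2_mmhg, np.asarray(self.po2_anchors), np.log(np.asarray(self.k_anchors_pa_sn))
        )
        return float(np.exp(logk))

    def viscosity(self, po2_mmhg: float, shear_rate_per_s: float) -> float:
        """Effective viscosity eta = K * gdot**(n-1) (Pa s)."""
        if shear_rate_per_s <= 0:
            raise ValueError("shear rate must be > 0")
        return self.k_at(po2_mmhg) * shear_rate_per_s ** (self.n_at(po2_mmhg) - 1.0)

    def is_oxygen_independent(self) -> bool:
        return (
            len(set(self.n_anchors)) == 1 and len(set(self.k_anchors_pa_sn)) == 1
        )


@dataclass(frozen=True)
class BloodModelParams:
    """Tunable generator parameters behind :func:`build_blood_model`.

    The oxygenated consistency index gives eta(100/s) = 5 cP for sickle
    blood at the assay's fixed 25% HCT; the healthy value gives ~4 cP.
    Neither magnitude is published for this assay — they are package
    defaults, chosen as physiologically plausible.
    """

    n_anchors: Dict[float, float] = field(default_factory=lambda: dict(DEFAULT_N_ANCHORS))
    k_multipliers: Dict[float, float] = field(default_factory=lambda: dict(DEFAULT_K_MULTIPLIERS))
    k_oxygenated_pa_sn: float = 0.0151
    healthy_n: float = 0.76
    healthy_k_pa_sn: float = 0.012
    noise_cv: float = 0.05
    sensitivity: float = 1.0
    sickle_threshold_hbs: float = 0.7
    untransfused_reference_hbs: float = 0.9

    def sickle_model(self) -> BloodModel:
        po2 = sorted(self.n_anchors)
        for p in po2:
            if p not in self.k_multipliers:
                raise ValueError(f"no K multiplier for anchor at {p} mm Hg")
        n = [self.n_anchors[p] for p in po2]
        k = [self.k_multipliers[p] * self.k_oxygenated_pa_sn for p in po2]
        if not all(math.isfinite(v) and v > 0 for v in n + k):
            raise ValueError("anchors must be finite and positive")
        return BloodModel(
            po2_anchors=tuple(po2),
            n_anchors=tuple(n),
            k_anchors_pa_sn=tuple(k),
            sensitivity=self.sensitivity,
            noise_cv=self.noise_cv,
            label="sickle",
        )

    def healthy_model(self) -> BloodModel:
        return BloodModel(
            po2_anchors=(0.0,),
            n_anchors=(self.healthy_n,),
            k_anchors_pa_sn=(self.healthy_k_pa_sn,),
            sensitivity=self.sensitivity,
            noise_cv=self.noise_cv,
            label="healthy",
        )


def build_blood_model(
    composition: SampleComposition, params: BloodModelParams = BloodModelParams()
) -> BloodModel:
    """Material law for a sample, from its hemoglobin composition.

    Untransfused sickle blood (HbS above ``params.sickle_threshold_hbs``)
    gets the anchored oxygen-dependent law; HbS = 0 gets the oxygen-
    independent healthy law; intermediate HbS fractions get the nonlinear
    mixture law of :func:`mixture_blood_model`.
    """
    sickle = params.sickle_model()
    if composition.hbs >= params.sickle_threshold_hbs:
        return sickle
    healthy = params.healthy_model()
    if composition.hbs == 0.0:
        return healthy
    return mixture_blood_model(
        sickle,
        healthy,
        hbs_mass_fraction=composition.hbs,
        sensitivity=params.sensitivity,
        untransfused_hbs=params.untransfused_reference_hbs,
    )


def mix_transfusion(
    sickle: SampleComposition, donor: SampleComposition, sickle_volume_fraction: float
) -> SampleComposition:
    """Mix patient and donor blood at fixed HCT by hemoglobin mass balance.

    With both samples resuspended to the same hematocrit, mixing a volume
    fraction v of patient cells gives hemoglobin species mass fractions

        X_mix = (v * MCHC_s * X_s + (1-v) * MCHC_d * X_d)
                / (v * MCHC_s + (1-v) * MCHC_d)

    and mixture MCHC = v*MCHC_s + (1-v)*MCHC_d.  Total and per-species
    hemoglobin mass per unit blood volume are conserved exactly.
    """
    v = sickle_volume_fraction
    if not (0.0 <= v <= 1.0):
        raise ValueError("sickle volume fraction must lie in [0, 1]")
    if abs(sickle.hct - donor.hct) > 1e-9:
        raise ValueError("transfusion mixing assumes both samples fixed at the same HCT")
    if v == 0.0:
        return donor
    if v == 1.0:
        return sickle
    m_s, m_d = sickle.mchc_g_dl, donor.mchc_g_dl
    m_mix = v * m_s + (1.0 - v) * m_d

    def mix_frac(xs: float, xd: float) -> float:
        return (v * m_s * xs + (1.0 - v) * m_d * xd) / m_mix

    return SampleComposition(
        hct=sickle.hct,
        mchc_g_dl=m_mix,
        hbs=mix_frac(sickle.hbs, donor.hbs),
        hba=mix_frac(sickle.hba, donor.hba),
        hbf=mix_frac(sickle.hbf, donor.hbf),
    )


def transfusion_volume_fraction(
    sickle: SampleComposition, donor: SampleComposition, target_hbs: float
) -> float:
    """Patient volume fraction v achieving a target mixture HbS mass fraction.

    Inverts the mass balance analytically:
    v = target*MCHC_d / (MCHC_s*(HbS_s - target) + target*MCHC_d) for an
    HbS-free donor; the general form accounts for donor HbS too.
    """
    if not (0.0 <= target_hbs <= sickle.hbs):
        raise ValueError(
            f"target HbS {target_hbs} must lie in [donor level, patient level {sickle.hbs}]"
        )
    m_s, m_d = sickle.mchc_g_dl, donor.mchc_g_dl
    num = m_d * (target_hbs - donor.hbs)
    den = m_s * (sickle.hbs - target_hbs) + m_d * (target_hbs - donor.hbs)
    if den == 0:
        raise ValueError("degenerate mixing problem: patient and target HbS coincide")
    v = num / den
    if not (0.0 <= v <= 1.0):
        raise ValueError(f"no physical mixing ratio reaches HbS={target_hbs}")
    return float(v)


def mixture_blood_model(
    sickle_model: BloodModel,
    healthy_model: BloodModel,
    hbs_mass_fraction: float,
    sensitivity: float = 1.0,
    untransfused_hbs: float = 1.0,
) -> BloodModel:
    """Rheology of a transfusion mixture with patient-specific nonlinearity.

    The sickle-side weight is w = f**s where f is the HbS mass fraction
    normalized to the untransfused level and s >= 0 the patient sensitivity:
    s = 1 is linear mixing, s > 1 recovers healthy behavior early (healthy
    shape retained up to high HbS), s < 1 recovers late.  n mixes linearly
    and K geometrically (log-linearly) between the endpoint models.
    """
    if sensitivity < 0:
        raise ValueError("sensitivity must be >= 0")
    if not (0.0 <= hbs_mass_fraction <= 1.0):
        raise ValueError("HbS mass fraction must lie in [0, 1]")
    f = min(hbs_mass_fraction / untransfused_hbs, 1.0)
    if f == 0.0:
        return replace(healthy_model, sensitivity=sensitivity)
    if f == 1.0:
        return replace(sickle_model, sensitivity=sensitivity)
    w = f**sensitivity
    po2 = np.asarray(sickle_model.po2_anchors, dtype=float)
    n_mix = tuple(
        (1.0 - w) * healthy_model.n_at(p) + w * sickle_model.n_at(p) for p in po2
    )
    k_mix = tuple(
        float(
            np.exp(
                (1.0 - w) * np.log(healthy_model.k_at(p)) + w * np.log(sickle_model.k_at(p))
            )
        )
        for p in po2
    )
    return BloodModel(
        po2_anchors=tuple(po2),
        n_anchors=n_mix,
        k_anchors_pa_sn=k_mix,
        sensitivity=sensitivity,
        noise_cv=sickle_model.noise_cv,
        label=f"mixture(f={f:.3g}, s={sensitivity:g})",
    )


# ---------------------------------------------------------------------------
# forward device model
# ---------------------------------------------------------------------------


def default_network() -> DeviceNetwork:
    """Illustrative default device: 15 um square experimental/bypass channels
    (8 mm, the experimental-zone length) and a 15 x 45 um x 50 mm rectangular
    inlet dissipater.  The real mask's resistor geometry is unpublished, so
    these defaults are physically coherent stand-ins, not measured values.
    """
    square = ChannelGeometry(15e-6, 15e-6, 8e-3, "square")
    inlet = ChannelGeometry(15e-6, 45e-6, 50e-3, "rectangular")
    return DeviceNetwork(
        inlet_resistor=HydraulicResistor.from_geometry("inlet_resistor", inlet),
        bypass=HydraulicResistor.from_geometry("bypass", square),
        experimental=HydraulicResistor.from_geometry("experimental", square),
    )


def default_pressure_steps(n_steps: int = 8) -> np.ndarray:
    """Log-spaced driving pressures (Pa) spanning average shear rates ~20-500/s
    for the default blood model in the default device."""
    return np.geomspace(1.8e3, 2.0e4, n_steps)


def _section_viscosities(
    model: BloodModel,
    network: DeviceNetwork,
    po2: float,
    q_total: float,
    q_exp: float,
    settings: InversionSettings,
) -> Tuple[float, float, float]:
    """Shear-dependent section viscosities for the continuity velocity rule."""
    f = settings.profile_factor
    g1_geo = network.inlet_resistor.geometry
    g2_geo = network.bypass.geometry
    g3_geo = network.experimental.geometry
    u1 = q_total / (f * g1_geo.area_m2)
    u2 = (q_total - q_exp) / (f * g2_geo.area_m2)
    u3 = q_exp / (f * g3_geo.area_m2)
    g1 = u1 / g1_geo.half_height_m
    g2 = u2 / g2_geo.half_height_m
    g3 = u3 / g3_geo.half_height_m
    return (
        model.viscosity(po2, g1),
        model.viscosity(po2, g2),
        model.viscosity(po2, g3),
    )


def forward_operating_point(
    model: BloodModel,
    network: DeviceNetwork,
    pressure_pa: float,
    po2_mmhg: float,
    settings: InversionSettings = InversionSettings(),
) -> Dict[str, float]:
    """Solve the nonlinear forward circuit problem for one pressure step.

    Finds the total flow Q (and its branch split) such that the circuit
    pressure drop with shear-dependent section viscosities equals the applied
    pressure, by bracketed root finding (outer: Q_total; inner: branch split
    at equal branch pressure drop).  Returns the operating point, including
    the midline velocity that the camera would record.
    """
    if pressure_pa <= 0:
        raise ValueError("pressure must be > 0")
    if not network.has_geometries():
        raise ValueError("forward model requires geometries on all three resistors")
    f = settings.profile_factor
    a3 = network.experimental.geometry.area_m2

# root finding happens in scaled variables (branch fraction, Q relative to a
    # Newtonian guess): absolute flows are ~1e-13 m^3/s, far below brentq's
    # default absolute xtol.

    def split(q_total: float) -> float:
        """Experimental flow Q3 at equal branch pressure drops."""

        def imbalance(s: float) -> float:
            q3 = s * q_total
            q2 = q_total - q3
            _, eta2, eta3 = _section_viscosities(
                model, network, po2_mmhg, q_total, q3, settings
            )
            return network.c2 * eta2 * q2 - network.c3 * eta3 * q3

        s = brentq(imbalance, 1e-12, 1.0 - 1e-12, xtol=1e-15, rtol=1e-15, maxiter=200)
        return s * q_total

    # bracket around the Newtonian estimate at a representative viscosity
    eta_ref = model.viscosity(po2_mmhg, 100.0)
    r_newt = network.c1 * eta_ref + (
        (network.c2 * eta_ref * network.c3 * eta_ref)
        / (network.c2 * eta_ref + network.c3 * eta_ref)
    )
    q_guess = pressure_pa / r_newt

    def pressure_residual(x: float) -> float:
        q_total = x * q_guess
        q3 = split(q_total)
        eta1, eta2, eta3 = _section_viscosities(
            model, network, po2_mmhg, q_total, q3, settings
        )
        dp = q_total * network.c1 * eta1 + q3 * network.c3 * eta3
        return dp - pressure_pa

    lo, hi = 1.0, 1.0
    for _ in range(80):
        if pressure_residual(lo) < 0:
            break
        lo /= 2.0
    else:  # pragma: no cover
        raise RuntimeError(f"failed to bracket Q from below at dp={pressure_pa} Pa")
    for _ in range(80):
        if pressure_residual(hi) > 0:
            break
        hi *= 2.0
    else:  # pragma: no cover
        raise RuntimeError(f"failed to bracket Q from above at dp={pressure_pa} Pa")
    q_total = q_guess * brentq(pressure_residual, lo, hi, xtol=1e-14, rtol=1e-14, maxiter=200)
    q3 = split(q_total)
    eta1, eta2, eta3 = _section_viscosities(model, network, po2_mmhg, q_total, q3, settings)
    umax = q3 / (f * a3)
    g3 = umax / network.experimental.geometry.half_height_m
    return {
        "pressure_pa": pressure_pa,
        "po2_mmhg": po2_mmhg,
        "q_total_m3_s": q_total,
        "q_experimental_m3_s": q3,
        "umax_m_s": umax,
        "shear_rate_per_s": g3,
        "eta1_pa_s": eta1,
        "eta2_pa_s": eta2,
        "eta3_pa_s": eta3,
    }


def generate_trace(
    model: BloodModel,
    network: DeviceNetwork,
    pressure_steps_pa: Sequence[float],
    oxygen_schedule_mmhg: Sequence[float] = DEFAULT_OXYGEN_TENSIONS,
    replicates: int = 18,
    seed: int = 0,
    step_duration_s: float = 20.0,
    settings: InversionSettings = InversionSettings(),
    include_transient: bool = True,
    sample_id: str = "synthetic",
) -> Tuple[RheologyTrace, Dict]:
    """Forward-simulate a pressure-step trace for one sample.

    For each oxygen tension in the schedule and each pressure step, the
    nonlinear forward model yields the steady midline velocity; the emitted
    records are ``replicates`` noisy captures (multiplicative Gaussian, CV
    from the model) time-stamped inside the steady-state second half of the
    step, optionally preceded by transient captures relaxing from the
    previous step that downstream windowing must reject.

    Returns the trace and a ground-truth dict (per-tension n, K and the
    noiseless operating points).
    """
    steps = np.asarray(pressure_steps_pa, dtype=float)
    if steps.size == 0:
        raise ValueError("need at least one pressure step")
    if np.any(steps <= 0):
        raise ValueError("pressures must be > 0")
    if replicates < 1:
        raise ValueError("need at least one replicate per step")
    rng = np.random.default_rng(seed)

    rows = []
    truth: Dict = {"sample_id": sample_id, "seed": int(seed), "per_tension": {}}
    t0 = 0.0
    prev_u = None
    for po2 in oxygen_schedule_mmhg:
        tension_truth = {
            "n": model.n_at(po2),
            "K_pa_sn": model.k_at(po2),
            "steps": [],
        }
        for dp in steps:
            op = forward_operating_point(model, network, float(dp), float(po2), settings)
            u_steady = op["umax_m_s"] * 1e6  # um/s
            tension_truth["steps"].append(
                {
                    "pressure_pa": float(dp),
                    "umax_um_s": u_steady,
                    "shear_rate_per_s": op["shear_rate_per_s"],
                    "eta3_pa_s": op["eta3_pa_s"],
                }
            )
            rep_id = 0
            if include_transient:
                n_trans = max(replicates // 2, 1)
                u_from = prev_u if prev_u is not None else 0.5 * u_steady
                tau = 0.1 * step_duration_s
                t_trans = t0 + step_duration_s * np.linspace(0.05, 0.45, n_trans)
                for t in t_trans:
                    u_t = u_steady + (u_from - u_steady) * math.exp(-(t - t0) / tau)
                    noise = 1.0 + model.noise_cv * rng.standard_normal()
                    rows.append(
                        (float(t), float(dp), float(po2), max(u_t * noise, 0.0), rep_id)
                    )
                    rep_id += 1
            t_steady = t0 + step_duration_s * np.linspace(0.55, 0.95, replicates)
            for t in t_steady:
                noise = 1.0 + model.noise_cv * rng.standard_normal()
                rows.append(
                    (float(t), float(dp), float(po2), max(u_steady * noise, 0.0), rep_id)
                )
                rep_id += 1
            prev_u = u_steady
            t0 += step_duration_s
        truth["per_tension"][float(po2)] = tension_truth

    df = pd.DataFrame(rows, columns=["time_s", "pressure_pa", "po2_mmhg", "umax_um_s", "replicate"])
    trace = RheologyTrace(records=df, sample_id=sample_id)
    return trace, truth


@dataclass(frozen=True)
class CohortSpec:
    """Specification for a synthetic patient cohort."""

    n_patients: int = 9
    seed: int = 0
    between_subject_sd: Dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_BETWEEN_SUBJECT_SD)
    )
    pressure_steps_pa: Tuple[float, ...] = tuple(default_pressure_steps())
    oxygen_tensions_mmhg: Tuple[float, ...] = DEFAULT_OXYGEN_TENSIONS
    replicates_per_step: int = 18
    n_truncation: Tuple[float, float] = (0.3, 1.3)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("cohort needs at least one patient")
        if self.replicates_per_step < 1:
            raise ValueError("need at least one replicate per step")


def generate_cohort(
    spec: CohortSpec,
    base_model: Optional[BloodModel] = None,
    network: Optional[DeviceNetwork] = None,
    settings: InversionSettings = InversionSettings(),
    include_transient: bool = True,
) -> Tuple[List[RheologyTrace], Dict]:
    """Generate one trace per synthetic patient plus the generating truth.

    Patient-to-patient variability enters through the flow-behavior-index
    anchors only: each patient's anchor at each oxygen tension is drawn
    Normal(population anchor, between-subject SD), truncated to
    ``spec.n_truncation`` by redrawing.  Consistency-index anchors are shared.
    All randomness (anchor draws and replicate noise) derives from
    ``spec.seed``.
    """
    if base_model is None:
        base_model = BloodModelParams().sickle_model()
    if network is None:
        network = default_network()
    ss = np.random.SeedSequence(spec.seed)
    anchor_rng = np.random.default_rng(ss.spawn(1)[0])
    trace_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(spec.n_patients)]

    po2_anchor = np.asarray(base_model.po2_anchors, dtype=float)
    lo, hi = spec.n_truncation
    traces: List[RheologyTrace] = []
    truth: Dict = {"seed": int(spec.seed), "patients": []}
    for i in range(spec.n_patients):
        n_i = []
        for p, n_pop in zip(po2_anchor, base_model.n_anchors):
            sd = spec.between_subject_sd.get(float(p), 0.0)
            draw = n_pop
            if sd > 0:
                draw = float(anchor_rng.normal(n_pop, sd))
                while not (lo < draw < hi):
                    draw = float(anchor_rng.normal(n_pop, sd))
            n_i.append(draw)
        model_i = replace(base_model, n_anchors=tuple(n_i), label=f"patient_{i+1}")
        trace, t_truth = generate_trace(
            model_i,
            network,
            spec.pressure_steps_pa,
            oxygen_schedule_mmhg=spec.oxygen_tensions_mmhg,
            replicates=spec.replicates_per_step,
            seed=trace_seeds[i],
            settings=settings,
            include_transient=include_transient,
            sample_id=f"patient_{i+1}",
        )
        traces.append(trace)
        truth["patients"].append(
            {
                "sample_id": f"patient_{i+1}",
                "n_anchors": {float(p): n for p, n in zip(po2_anchor, n_i)},
                "trace_seed": trace_seeds[i],
                "trace_truth": t_truth,
            }
        )
    return traces, truth
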