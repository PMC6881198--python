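# Methods

This note records the models, numerical choices and open design decisions
behind `oxyrheo`, at the level of detail a maintainer (or skeptical user)
needs to judge what the package's outputs do and do not mean.

## Hydraulic circuit model

The blood layer of the device is treated as three laminar resistors: an
inlet "pressure dissipater" (R₁) in series with the parallel pair of the
bypass (R₂) and experimental (R₃) channels. Each resistance is `R = c·η`
with a geometric constant `c` (1/m³) from the standard duct formulas

- square (h = w): `R = 12ηL / (0.422·h⁴)`
- shallow rectangular (h ≤ w): `R = 12ηL / [(1 − 0.63·h/w)·h³w]`

The two formulas disagree by 0.422/0.37 ≈ 1.14 at h = w, so square
channels are always routed to the square formula; the rectangular one is
reserved for genuinely wide channels and raises on h > w. Validity of the
resistor picture rests on Re ≪ 1: blood at the fastest observed midline
velocity (3.5 mm/s) in a 15 µm channel gives Re ≈ 0.014.

**Units.** SI internally throughout. Oxygen tension stays in mm Hg as a
labelled quantity (160 ≈ ambient, 0 = anoxic). Viscosities are Pa·s in
memory; 1 mPa·s = 1 cP for reporting.

**Default geometry is illustrative.** The published device specifies the
15 µm × 15 µm cross-section and ~8 mm experimental-zone length but not the
dissipater geometry or the numeric c₁, c₂, c₃. The packaged defaults
(experimental/bypass: 15 µm square × 8 mm; dissipater: 15 × 45 µm × 50 mm
rectangular, i.e. c₁ ≈ 5.0×10¹⁸, c₂ = c₃ ≈ 4.5×10¹⁸ m⁻³) were chosen so
that the default pressure protocol (1.8–20 kPa, within a 15-psig
regulator's range) spans average shear rates of roughly 20–500 s⁻¹ for
oxygenated blood — physically coherent, but not measured values. Configs
may instead supply c constants directly; section shear-rate allocation
(hence non-trivial A, B) then requires geometries and falls back to
A = B = 1 with a logged warning.

## Rheogram inversion

Per oxygen tension, replicate velocities are averaged within the
steady-state window of each pressure step (the trailing 50% of the step's
observed time span by default, mirroring the protocol of letting each step
equilibrate before capturing video). Then:

1. initialize A = B = 1;
2. per step: `Q₃ = f·u_max·h·w` with profile factor f = 0.477 (the laminar
   square-duct mean-to-maximum velocity ratio, verified in-tests against
   the Fourier-series duct profile), `Q_total = Q₃·(1 + c₃/(c₂B))`,
   and η₃ from the closed-form inversion;
3. fit a provisional power law across the curve (slope n);
4. update per-step `A = (γ̇₁/γ̇₃)ⁿ⁻¹`, `B = (γ̇₂/γ̇₃)ⁿ⁻¹` from section
   shear rates;
5. iterate until the max relative change in η₃ is < 1e-8 (≤ 100
   iterations, with 0.5 damping if the update oscillates). Convergence
   failures raise, carrying the last iterate for diagnosis.

**Velocity-allocation rule.** The original analysis linearizes by assuming
section velocities proportional to cross-sectional area; that assumption
is not mass-conserving across the branch point. The default rule
("continuity") instead derives section mean velocities from flow
continuity — the inlet carries Q_total, branches split at equal branch
pressure drop — and `γ̇ᵢ = uᵢ/(hᵢ/2)`. The literal area-proportional rule
is available as `velocity_rule: area_proportional`; on synthetic data the
two agree on n to within a few hundredths but differ measurably in K, and
the package logs when geometries permit the comparison. How A and B were
numerically generated "between each shear rate step" in the original
analysis is not specified; the global provisional-power-law update here is
a reconstruction and is flagged as such.

**One material law per trace.** The forward generator applies the blood
model at the trace's recorded oxygen tension to all three sections. In the
physical device the bypass and dissipater stay normoxic, which would make
A and B depend on oxygen as well as shear; the single-law convention
mirrors the inversion's own assumption (A, B as pure shear-rate ratios)
and makes the round trip well-posed. Consequences for real data: if the
normoxic-bypass effect matters, it shifts K (a near-constant factor within
one tension) far more than n, which is the quantity the pipeline reports
against references.

**Uncertainty.** Replicate scatter propagates to the rheogram through the
first-order sensitivity of the closed-form inversion (δη₃/η₃ ≈ −δu/u at
fixed A, B); reported bars are the measurement SD, not the SE.

## Power-law fitting

`fit_power_law` is OLS of log₁₀τ on log₁₀γ̇: slope = n, intercept =
log₁₀K, and the reported goodness of fit is the R² of that linear fit —
the original figure plots a "goodness of fit" without defining it, so R²
in fitting space is adopted and documented here as the package's choice.
Unweighted by default (no weighting is described for the original
analysis); inverse-variance weighting from replicate SDs is available.
The log base only shifts the intercept bookkeeping, not n or R².
Yield-stress models (Herschel–Bulkley, Casson) are out of scope, though
the elevated scatter of power-law fits at 0 mm Hg suggests them as an
extension.

## Oxygen transport

The 3-D device is reduced to its dominant vertical transport path: a 1-D
stack (bottom → top) of blood 15 µm, PDMS membrane 100 µm, hydration
100 µm, PDMS membrane 100 µm, with D_PDMS = 3.3×10⁻⁵ and D_water =
4×10⁻⁵ cm²/s, a no-flux bottom (glass slide), and a Dirichlet top at the
gas-protocol tension. No PDMS/water solubility partitioning is applied —
the reference model specifies diffusion coefficients only — so the field
is pure Fickian diffusion with piecewise D, carried in mm Hg.

Discretization: finite-volume cells on a uniform grid (default 1 µm;
the thinnest layer must get ≥ 5 nodes), harmonic-mean interface
diffusivities, backward Euler at Δt = 0.05 s. Backward Euler was chosen
over Crank–Nicolson deliberately: it is L-stable and its update matrix is
an M-matrix, so the computed field relaxes monotonically after a switch
and stays positive — Crank–Nicolson oscillates at this mesh ratio
(D·Δt/Δz² ≈ 200) on the discontinuous boundary step. With both boundaries
sealed the scheme conserves the integrated field to round-off, which the
test suite uses as a solver self-check. An explicit scheme is included for
cross-validation and refuses to run outside its stability bound. Accuracy:
against the single-slab cosine-series solution the solver is within 0.5%
at Δt = 5 ms, and the default-resolution time-to-anoxia changes by < 2%
under grid halving.

"Reached 0 mm Hg" is operationalized as the blood-layer midpoint crossing
2 mm Hg (1.25% of ambient, configurable). With the default stack this
gives ≈ 53 s after a 160→0 switch, consistent with the measured ~60 s;
agreement is only claimed within a factor of 2, because the 1-D reduction
drops the lateral PDMS walls (open to ambient air) and in-plane transport.
Ru(bpy)₃ calibration defaults to Stern–Volmer (`I₀/I = 1 + K_sv·pO₂`,
two-point), since collisional quenching is physically hyperbolic; a linear
two-point alternative is provided because the original calibration method
is not stated.

## Synthetic blood and cohorts

The generator's material law is `τ = K(pO₂)·γ̇^n(pO₂)`:

- **n anchors (untransfused sickle, HbS > 0.7):** (92, 0.76), (46, 0.74),
  (0, 0.87), piecewise linear in pO₂, constant above 92. These are the
  measured cohort means and are the quantities the pipeline must return.
- **K anchors:** K_ox = 0.0151 Pa·sⁿ (η(100 s⁻¹) = 5 cP at the assay's
  fixed 25% HCT) times multipliers (1.0, 1.35, 1.9) at 92/46/0 mm Hg,
  interpolated log-linearly. No viscosity magnitudes are published for
  this assay, so these are plausibility defaults: they enforce the
  observed strict ordering of viscosity with deoxygenation at 100 s⁻¹,
  and recovery tests target n, not absolute K.
- **Healthy blood (HbS = 0):** oxygen-independent by construction, with
  n = 0.76 (no healthy index is published; transfusion is described as
  restoring the *shape* of the sickle oxygenated curve) and K = 0.012
  Pa·sⁿ (≈ 4 cP at 100 s⁻¹). Intermediate HbS uses the mixture law below.
- **Noise:** multiplicative Gaussian on velocity, CV 5%, 18 replicates per
  pressure step, matching the ~18 video captures per step of the protocol;
  each step also emits transient captures (exponential settling over the
  first half of the step) that the inversion's steady-state window must
  discard.
- **Cohorts:** 9 patients; per-patient n anchors drawn
  Normal(anchor, SD) with the observed between-subject SDs
  (0.075, 0.049, 0.056 at 92/46/0 mm Hg), truncated to (0.3, 1.3) by
  redraw. K anchors are shared. All randomness flows from one seed
  (SeedSequence-spawned per patient); ground truth is always emitted.

The forward device model solves the nonlinear circuit (shear-dependent
section viscosities, continuity flow split) for Q by bracketed root
finding — in scaled variables, since absolute flows (~10⁻¹³ m³/s) are far
below scipy's default absolute tolerance. Because all sections share one
power law, Δp ∝ Qⁿ exactly, which the tests exploit as a closed-form check.

**What the generator does not emulate:** hematocrit drift, cell adhesion
and occlusion events, yield-stress behavior at 0 mm Hg, intra-step
polymerization kinetics, or oxygen dependence of the bypass sections.
Passing round-trip tests therefore demonstrates correctness of the
inversion chain under the stated material model — not that real sickle
blood is a clean power-law fluid.

**Transfusion.** Mixtures are computed at fixed 25% HCT by hemoglobin mass
balance: species fraction `(v·MCHC_s·X_s + (1−v)·MCHC_d·X_d)/(v·MCHC_s +
(1−v)·MCHC_d)`; conservation is exact and tested to 1e-12. Mixture
rheology interpolates n linearly and K geometrically between sickle and
healthy endpoints with sickle weight `w = f^s` (f = HbS fraction relative
to the untransfused level): s = 1 linear, s > 1 early recovery of healthy
behavior, s < 1 late recovery — the knob that reproduces the
patient-to-patient differences seen in simulated-transfusion experiments.

## Cohort statistics

Friedman's test on the complete patients × conditions block (within-block
average ranks, tie-corrected statistic, k−1 df). The p-value is exact —
full within-block permutation null, computed by dynamic programming over
column rank-sum vectors — whenever (k!)ⁿ ≤ 10⁶, else the χ² asymptotic;
at the 9 × 3 design the asymptotic test's realized type-I error is ≈ 5%
(verified by simulation in the suite). Post-hoc pairs default to the
exact paired sign-permutation test (statistic |Σ signed differences|, all
2ⁿ sign patterns), Bonferroni-multiplied by the number of pairs and capped
at 1; Wilcoxon signed-rank is available as an alternative. The exact
procedure behind the original figure's asterisks is not stated, so the
pattern (92 vs 46 NS; 0 mm Hg significant against both) is asserted on
synthetic cohorts as a stochastic property over seeds, not per seed.
Pearson correlations use the t-transform two-sided p (n−2 df), whose null
uniformity at n = 9 is verified by simulation.

## Problem sizes and defaults

Default analyses are desk-scale by design: 9 patients × 3 tensions ×
8 pressure steps × 18 replicates inverts in well under a second, the
diffusion solver integrates 150 s of the 315 µm stack at (1 µm, 0.05 s)
in ~0.2 s, and the full test suite (including 10⁴-replicate null
calibrations and a 10⁵-draw Pearson null) runs in seconds. The
acceptance script reruns the entire chain from scratch at these sizes.

## Known limitations

- Entrance/transition losses, PDMS wall compliance and temperature
  dependence of viscosity are neglected in the circuit model.
- The dissipater geometry (hence c₁) is a stand-in; absolute viscosities
  from default configs are only as good as the supplied constants.
- The 1-D oxygen model under-counts lateral oxygen supply; its timescale
  is a factor-2 statement.
- Cohort-mean recovery inherits the sampling error of a 9-patient draw
  (SE ≈ 0.017–0.025 on n), which dominates the pipeline's own bias
  (< 0.005) at any single seed.
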