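device:
  profile_factor: 0.477
  velocity_rule: continuity
  channels:
    inlet_resistor:
      shape: rectangular
      height_um: 15.0
      width_um: 45.0
      length_mm: 50.0
    bypass:
      shape: square
      height_um: 15.0
      width_um: 15.0
      length_mm: 8.0
    experimental:
      shape: square
      height_um: 15.0
      width_um: 15.0
      length_mm: 8.0
protocol:
  pressure_steps_pa:
  - 1800.0
  - 2539.022
  - 3581.462
  - 5051.895
  - 7126.039
  - 10051.761
  - 14178.689
  - 20000.0
  oxygen_tensions_mmhg:
  - 92.0
  - 46.0
  - 0.0
  step_duration_s: 20.0
generator:
  noise_cv: 0.05
  replicates_per_step: 18
  blood:
    hct: 0.25
    mchc_g_dl: 33.0
    hbs: 1.0
    n_anchors:
      '92': 0.76
      '46': 0.74
      '0': 0.87
    k_multipliers:
      '92': 1.0
      '46': 1.35
      '0': 1.9
    k_oxygenated_pa_sn: 0.0151
    healthy_n: 0.76
    healthy_k_pa_sn: 0.012
  cohort:
    n_patients: 9
    between_subject_sd:
      '92': 0.075
      '46': 0.049
      '0': 0.056
solver:
  fixed_point:
    tol: 1.0e-08
    max_iter: 100
    damping: 0.5
    steady_state_fraction: 0.5
  diffusion:
    dz_um: 1.0
    dt_s: 0.05
    scheme: implicit
    anoxia_threshold_mmhg: 2.0
    layers:
    - name: blood
      thickness_um: 15.0
      material: water
    - name: membrane_lower
      thickness_um: 100.0
      material: pdms
    - name: hydration
      thickness_um: 100.0
      material: water
    - name: membrane_upper
      thickness_um: 100.0
      material: pdms
    diffusion_coefficients_cm2_s:
      pdms: 3.3e-05
      water: 4.0e-05
stats:
  alpha: 0.05
  posthoc: sign_permutation
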