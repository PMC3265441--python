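# Type 3 capsule (control): tip radius 4 mm, maximum diameter 11 mm, slope 0.3/mm.
#
# Tissue, drag and mass values below are calibration inputs: the source
# contraction experiments fix mu = 0.1, tau_s = 17.3 s and the
# relaxation spectrum, but never report the resting lumen diameter,
# wall thickness, drag coefficient or capsule mass.  The bundled values
# are a documented calibration (see docs/methods.md): d0/h are
# physiologically plausible for porcine small intestine, stress_scale
# sits between the two published spectrum scalings and is set so the
# type-3 control capsule stays immobile, b and mass are conventional
# telemetry-capsule figures.
schema_version: 1
mass_g: 3.8
shape:
  r_mm: 4.0
  R_mm: 5.5
  alpha_per_mm: 0.3
  L_mm: 26.0
tissue:
  d0_mm: 8.0
  h_mm: 0.6
  mu: 0.1
  relax_amplitudes_kpa: [0.7, 0.63, 0.92]
  relax_taus_s: [18.0, 1.6]
  stress_scale: 5.0
  tau_s_s: 17.3
  strain_mode: diameter_ratio
  relaxation_mode: measured
stimulus:
  amplitude_v: 6.0
  frequency_hz: 10.0
  pulse_ms: 5.0
  electrode_offset_mm: 5.0
  footprint_variance_cm2: 0.22
  footprint_amplitude: 1.4
drag:
  mode: constant
  b_mn_s_per_mm: 0.5
solver:
  dt_s: 0.001
  duration_s: 60.0
  grid_dx_mm: 0.25
  decimation: 10
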