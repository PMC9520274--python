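# Frozen default parameter set for the coated-microbubble simulation.
#
# Medium: water-like buffer at ambient conditions. Gas: perfluorobutane
# core, quasi-adiabatic polytropic exponent. Shell: chi / kappa_s /
# initial tension were frozen by sonokit.bubble_dynamics.calibrate_shell
# against five expansion-ratio and regime-boundary anchors at 250 kHz
# (see docs/methods.md); they are effective fitted values, not measured
# material constants.
bubble:
  resting_radius_um: 0.75
gas:
  polytropic_exponent: 1.07
  vapor_pressure_pa: 0.0
medium:
  density_kg_m3: 1000.0
  dynamic_viscosity_pa_s: 0.001
  sound_speed_m_s: 1500.0
  ambient_pressure_kpa: 101.325
  water_surface_tension_n_m: 0.073
shell:
  elastic_modulus_chi_n_m: 0.016337
  surface_viscosity_kappa_s_kg_s: 6.2077e-09
  initial_surface_tension_n_m: 0.053570
drive:
  center_frequency_mhz: 0.25
  pnp_kpa: 0.0
  n_cycles: 50
  envelope: rectangular
thresholds:
  stable_lower: 1.1
  inertial_onset: 3.5
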