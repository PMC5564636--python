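# Example run configuration: virtual tumor-bearing adult, 350 mg/m2
# irinotecan infused over 30 min, 100-subject mixed-sex population.
seed: 1
compounds: ["builtin:cpt11", "builtin:sn38", "builtin:sn38g"]
individual: {sex: male, age: 55.0}
population:
  n_individuals: 100
  female_fraction: 0.5
regimen: {compound: CPT-11, dose_per_bsa: 350.0, infusion_duration: 30.0}
network: {cl_int_ce: 0.065, cl_int_ugt: 3.0}
simulation: {t_end: 25.5, grid_step: 0.02, method: expm}
calibration:
  free_parameters: [cl_int_ce, cl_int_ugt, biliary]
ph_scan:
  plasma: [6.0, 6.5, 7.0, 7.5]
  tumor: [6.0, 6.5, 7.0, 7.5]
output_dir: out
log_level: INFO
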