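# Irinotecan (CPT-11) physicochemical and clearance parameters.
name: CPT-11
molecular_weight: 677.10          # g/mol
effective_molecular_weight: 655.10
log_p: 2.78                       # log units
fraction_unbound: 0.32
pka_acid: 11.71
pka_base: 9.47
solubility_at_ph7: 0.11           # mg/ml
gfr_fraction: 1.0
specific_biliary_clearance: 2.70  # ml/min/kg
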