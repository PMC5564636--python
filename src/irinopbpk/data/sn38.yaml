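# SN-38 (7-ethyl-10-hydroxycamptothecin), active metabolite of irinotecan.
name: SN-38
molecular_weight: 392.40          # g/mol
effective_molecular_weight: 392.40
log_p: 1.87                       # log units
fraction_unbound: 0.05
pka_acid: 9.68
pka_base: 3.91
solubility_at_ph7: 0.29           # mg/ml
gfr_fraction: 1.0
specific_biliary_clearance: 2.70  # ml/min/kg
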