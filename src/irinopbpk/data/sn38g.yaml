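# SN-38G, the inactive glucuronide of SN-38 (UGT1A1/1A6/1A9 product).
# No published parameter table exists for this species; values below are
# documented assumptions: MW = SN-38 + glucuronic acid - H2O, a strongly
# reduced lipophilicity, weaker plasma binding, and elimination by both
# glomerular filtration and bile, as expected of a polar glucuronide.
name: SN-38G
molecular_weight: 568.53          # g/mol
effective_molecular_weight: 568.53
log_p: 0.20                       # log units (assumed, polar conjugate)
fraction_unbound: 0.30            # assumed
pka_acid: 3.10                    # glucuronic acid carboxyl (assumed)
pka_base: 3.91
solubility_at_ph7: 1.0            # mg/ml (assumed, water-soluble)
gfr_fraction: 1.0
specific_biliary_clearance: 2.70  # ml/min/kg (assumed equal to parent)
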