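# Illustrative cohort profile: higher CYP2D6 no-function frequency (CYP2D6
# PM near 4%, so paroxetine/fluvoxamine actionable exceed the qgp_like
# profile) and lower CYP2B6 deficiency (sertraline actionable near 33%).
# Synthetic calibration values, not published allele frequencies.
label: eu_like
genes:
  CYP2C19: {"*1": 0.72, "*17": 0.22, "*2": 0.06}
  CYP2D6: {"*1": 0.50, "*2": 0.12, "*4": 0.18, "*10": 0.08, "*41": 0.12}
  CYP2B6: {"*1": 0.85, "*6": 0.12, "*18": 0.02, "*4": 0.01}
  CYP3A4: {"*1": 0.95, "*20": 0.03, "*22": 0.02}
cyp2d6_cn:
  deletion: 0.03
  duplication: 0.03
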