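# Illustrative cohort profile: higher CYP2D6 decreased-function frequency
# (modal TCA recommendation = 25% starting-dose reduction) and higher
# CYP2B6 deficiency (sertraline actionable near 51%). Synthetic calibration
# values, not published allele frequencies.
label: onekg_like
genes:
  CYP2C19: {"*1": 0.82, "*17": 0.06, "*2": 0.12}
  CYP2D6: {"*1": 0.45, "*2": 0.10, "*10": 0.30, "*41": 0.10, "*4": 0.05}
  CYP2B6: {"*1": 0.78, "*6": 0.17, "*18": 0.04, "*4": 0.01}
  CYP3A4: {"*1": 0.975, "*20": 0.015, "*22": 0.01}
cyp2d6_cn:
  deletion: 0.02
  duplication: 0.02
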