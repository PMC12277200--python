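# Illustrative cohort profile: high CYP2C19 increased-function frequency
# (citalopram/escitalopram actionable near 58%, modal TCA recommendation =
# alternative drug not metabolized by CYP2C19) with moderate CYP2D6
# duplication rate. Frequencies are synthetic calibration values, not any
# population's published allele frequencies.
label: qgp_like
genes:
  CYP2C19: {"*1": 0.6426, "*17": 0.22, "*2": 0.1374}
  CYP2D6: {"*1": 0.40, "*2": 0.27, "*10": 0.22, "*4": 0.11}
  CYP2B6: {"*1": 0.83, "*6": 0.12, "*18": 0.03, "*4": 0.02}
  CYP3A4: {"*1": 0.968, "*20": 0.02, "*22": 0.012}
cyp2d6_cn:
  deletion: 0.02
  duplication: 0.09
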