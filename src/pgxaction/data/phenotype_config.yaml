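# Diplotype -> metabolizer-phenotype translation rules.
#
# CYP2D6 uses activity-score bins (half-open intervals; an entry covers
# scores in (previous_upper, upper], with the first bin covering exactly 0).
# The other genes use categorical rules keyed by the unordered pair of
# allele function classes ("a|b", sorted). Any allele of uncertain function
# short-circuits to Indeterminate before these rules apply.
cyp2d6_bins:
  - upper: 0.0
    phenotype: PM
  - upper: 1.0
    phenotype: IM
  - upper: 2.25
    phenotype: NM
  - upper: .inf
    phenotype: UM

categorical:
  CYP2C19:
    increased|increased: UM
    increased|normal: RM
    normal|normal: NM
    no_function|normal: IM
    increased|no_function: IM
    decreased|normal: IM
    decreased|increased: IM
    decreased|decreased: IM
    decreased|no_function: IM
    no_function|no_function: PM
  CYP2B6:
    increased|increased: UM
    increased|normal: NM
    decreased|increased: NM
    increased|no_function: IM
    normal|normal: NM
    decreased|normal: IM
    no_function|normal: IM
    decreased|decreased: PM
    decreased|no_function: PM
    no_function|no_function: PM
  CYP3A4:
    increased|increased: UM
    increased|normal: NM
    decreased|increased: NM
    increased|no_function: IM
    normal|normal: NM
    decreased|normal: IM
    no_function|normal: IM
    decreased|decreased: PM
    decreased|no_function: PM
    no_function|no_function: PM
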