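# Per-drug clinical actionability rules (CPIC / DPWG, PharmGKB Level 1A).
#
# Single-gene drugs list the metabolizer phenotypes that trigger a dosage
# change or alternative prescription. Two-gene drugs carry a total
# recommendation matrix over the non-Indeterminate phenotype pairs; a cell's
# category decides actionability (category S = standard care). Unprinted
# matrix cells are editable defaults informed by the consortium guideline
# wording; only the anchor cells pinned by that wording are treated as fixed.
#
# Paroxetine/vortioxetine actionable = {PM, UM} is a configured assumption
# defaulted from the CPIC SSRI guideline (flagged: assumption).
drugs:
  - drug: citalopram_escitalopram
    aliases: [citalopram, escitalopram]
    source: CPIC
    genes: [CYP2C19]
    actionable: [UM, RM, IM, PM]

  - drug: sertraline
    source: CPIC
    genes: [CYP2C19, CYP2B6]
    categories:
      S: {actionable: false, text: "Initiate therapy with recommended starting dose."}
      A: {actionable: false, text: "Initiate therapy with recommended starting dose; if response is inadequate, consider a higher maintenance dose or an alternative antidepressant not predominantly metabolized by CYP2C19 or CYP2B6."}
      B: {actionable: true, text: "Initiate therapy with recommended starting dose; consider a slower titration schedule and lower maintenance dose."}
      C: {actionable: true, text: "Initiate therapy with recommended starting dose; consider a slower titration schedule and lower maintenance dose than normal metabolizers."}
      D: {actionable: true, text: "Consider a lower starting dose, slower titration and 50% reduction of standard maintenance dose as compared to CYP2C19 normal metabolizers, or an alternative antidepressant not predominantly metabolized by CYP2C19."}
      E: {actionable: true, text: "Consider a lower starting dose, slower titration and 25% reduction of standard maintenance dose as compared to CYP2B6 normal metabolizers, or an alternative antidepressant not predominantly metabolized by CYP2B6."}
      F: {actionable: true, text: "Consider a lower starting dose, slower titration and 50% reduction of standard maintenance dose as compared to CYP2B6 normal metabolizers."}
      G: {actionable: true, text: "Select an alternative antidepressant not primarily metabolized by CYP2C19 or CYP2B6."}
    matrix:
      UM: {UM: A, NM: A, IM: C, PM: E}
      RM: {UM: A, NM: A, IM: C, PM: E}
      NM: {UM: A, NM: S, IM: C, PM: E}
      IM: {UM: B, NM: B, IM: C, PM: F}
      PM: {UM: D, NM: D, IM: D, PM: G}

  - drug: paroxetine
    source: CPIC
    genes: [CYP2D6]
    actionable: [PM, UM]
    assumption: true

  - drug: fluvoxamine
    source: CPIC
    genes: [CYP2D6]
    actionable: [PM]

  - drug: venlafaxine
    source: CPIC
    genes: [CYP2D6]
    actionable: [PM]

  - drug: vortioxetine
    source: CPIC
    genes: [CYP2D6]
    actionable: [PM, UM]
    assumption: true

  - drug: amitriptyline
    aliases: [clomipramine, doxepin, imipramine, trimipramine]
    source: CPIC
    genes: [CYP2C19, CYP2D6]
    categories:
      S: {actionable: false, text: "Initiate therapy with recommended starting dose."}
      A: {actionable: true, text: "Avoid amitriptyline use."}
      B: {actionable: true, text: "Consider alternative drug not metabolized by CYP2C19."}
      C: {actionable: true, text: "Avoid amitriptyline use; if amitriptyline is warranted, consider titrating to a higher target dose compared to normal metabolizers."}
      D: {actionable: true, text: "Avoid amitriptyline use; if amitriptyline is warranted, consider a 50% reduction of recommended starting dose."}
      E: {actionable: true, text: "Consider a 25% reduction of recommended starting dose."}
    matrix:
      UM: {UM: A, NM: B, IM: A, PM: A}
      RM: {UM: A, NM: B, IM: A, PM: A}
      NM: {UM: C, NM: S, IM: E, PM: D}
      IM: {UM: A, NM: S, IM: E, PM: D}
      PM: {UM: A, NM: B, IM: D, PM: A}

  - drug: aripiprazole_brexpiprazole
    aliases: [aripiprazole, brexpiprazole]
    source: DPWG
    genes: [CYP2D6]
    actionable: [PM]

  - drug: haloperidol
    source: DPWG
    genes: [CYP2D6]
    actionable: [PM, UM]

  - drug: risperidone
    source: DPWG
    genes: [CYP2D6]
    actionable: [PM, UM]

  - drug: pimozide
    source: DPWG
    genes: [CYP2D6]
    actionable: [PM, IM]

  - drug: zuclopenthixol
    source: DPWG
    genes: [CYP2D6]
    actionable: [PM, IM, UM]

  - drug: quetiapine
    source: DPWG
    genes: [CYP3A4]
    actionable: [PM]
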