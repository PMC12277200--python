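# pgxaction

A pharmacogenomic actionability pipeline for four psychotropic-relevant
pharmacogenes — CYP2C19, CYP2D6, CYP2B6 and CYP3A4 — covering thirteen
drug rules for SSRIs, tricyclic antidepressants and antipsychotics.

Given a cohort VCF (plus an optional per-sample CYP2D6 copy-number
sidecar), the pipeline:

1. **calls star-allele diplotypes** per sample and gene by matching
   alternate-allele dosages against a star-allele definition table
   (`allele_registry`, `star_caller`);
2. **translates diplotypes to metabolizer phenotypes** — activity-score
   binning for CYP2D6 (with copy-number multiplicity), function-class
   pair rules for the other genes (`phenotyper`);
3. **classifies per-drug actionability** under guideline-style rules,
   including combined-gene recommendation matrices for sertraline
   (CYP2C19 × CYP2B6) and the tricyclics (CYP2C19 × CYP2D6)
   (`guideline_engine`);
4. **compares cohorts** drug-by-drug with a pooled two-proportion
   z-test, Wald difference CI, odds ratio and Benjamini–Hochberg
   correction (`popstats`).

A Hardy–Weinberg cohort simulator with truth labels (`synthetic_data`)
supports calibration and end-to-end testing; three built-in frequency
profiles (`qgp_like`, `onekg_like`, `eu_like`) provide illustrative
population mixtures.

## Quick start

Simulate a 500-sample cohort and run the full pipeline:

```bash
pgxaction simulate --profile qgp_like --n 500 --seed 42 --out demo/sim
pgxaction run --vcf demo/sim/cohort.vcf --cn demo/sim/cohort.cn.tsv --out demo/report
head -6 demo/report/summary_a.tsv
```

```text
drug                     cohort    n    actionable_count  actionable_percent
citalopram_escitalopram  cohort_a  500  283               56.6
sertraline               cohort_a  500  226               45.2
paroxetine               cohort_a  500  43                8.6
fluvoxamine              cohort_a  500  9                 1.8
venlafaxine              cohort_a  500  9                 1.8
```

The report bundle also contains per-sample diplotypes
(`diplotypes_a.tsv`, with ambiguity flags and ranked alternatives),
phenotypes, the per-drug classification, and — when a second cohort is
supplied via `--vcf-b`/`--cn-b` — a `comparison.tsv` with z, raw and
BH-adjusted p-values, confidence intervals and odds ratios.

All outputs are timestamp-free: re-running on identical inputs is
byte-identical.

### Other subcommands

| command | purpose |
| --- | --- |
| `pgxaction call` | VCF (+ CN sidecar) → diplotype TSV |
| `pgxaction phenotype` | VCF → phenotype TSV |
| `pgxaction classify` | phenotype TSV → per-drug actionability |
| `pgxaction compare` | two classification TSVs → comparison table |
| `pgxaction landscape` | exhaustive diplotype → phenotype enumeration |

Every stage accepts `--alleles`, `--phenoconf` or `--rules` to swap in
custom star-allele tables, phenotype configurations or drug rules; the
shipped defaults live under `src/pgxaction/data/`.

## Testing and reproduction

```bash
pytest -q                                    # full suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the headline quantities from scratch —
published-count percentage arithmetic, simulated-cohort actionable
frequencies, phased diplotype recovery, Hardy–Weinberg fidelity of the
simulator, and Monte Carlo calibration (type-I error, power) of the
two-proportion z-test — and writes them as JSON.

See `docs/methods.md` for the underlying model, parameter choices and
limitations.
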