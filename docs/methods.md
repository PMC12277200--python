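# Methods

This document describes the models, parameter choices and numerical
conventions behind pgxaction, and what the synthetic data generator does
and does not emulate.

## Star-allele model and diplotyping

A star allele is a named haplotype of a pharmacogene defined by a fixed
multiset of variants (chromosome, 1-based position, ref, alt) plus a
curated function class (`normal`, `decreased`, `no_function`,
`increased`, `uncertain`) and, for CYP2D6, a numeric activity value.
`*1` is always the reference haplotype (no defining variants); CYP2D6
`*5` is the whole-gene deletion and also carries no defining variants —
it is never produced by variant matching, only by copy-number evidence.

The caller works at genotype level: for each gene it collects per-variant
alternate-allele dosages (0/1/2) and enumerates every unordered allele
pair whose combined defining-variant multiset exactly reproduces the
observed dosages. This exact-cover criterion conserves dosage by
construction (an allele pair that over- or under-explains any variant is
rejected). For fully phased samples the two haplotype variant sets are
matched independently, which removes phase ambiguity entirely.

When several pairs explain the data (possible only with unphased input
and overlapping allele definitions), one call is selected by ranking:

1. most observed variants attributed to non-reference alleles;
2. fewest distinct non-reference alleles;
3. numeric-aware lexicographic order of the pair label.

All unchosen candidates are retained as ranked alternatives and the call
is flagged `unphased_ambiguity`. A dosage pattern no pair explains is an
explicit no-call, never a silent default.

### Copy number

CYP2D6 copy number arrives as a per-sample sidecar (standing in for
read-depth structural-variant calling). cn=2 leaves the diploid call
unchanged; cn=0 is `*5/*5`; cn=1 keeps the surviving haplotype (which
presents at homozygous-like dosage) and pairs it with `*5`, flagging
`cn_ambiguity` when the diploid call was heterozygous; cn≥3 assigns the
extra copies to one allele under a policy (`higher` activity, `lower`,
or `ambiguous`), flagging the call whenever the assignment is not forced
(i.e., the two alleles differ).

## Phenotype assignment

CYP2D6 uses the activity-score convention: the score is the
multiplicity-weighted sum of allele activity values, binned as

| score | phenotype |
| --- | --- |
| 0 | PM |
| (0, 1] | IM |
| (1, 2.25] | NM |
| > 2.25 | UM |

The 1.0 boundary is assigned to IM so that one normal allele plus a null
(e.g. `*1/*5`) is intermediate, and 2.25 to NM so that a normal allele
plus a duplicated decreased allele stays normal. Any `uncertain` allele
makes the score, and hence the phenotype, `Indeterminate`.

CYP2C19, CYP2B6 and CYP3A4 use categorical translation keyed on the
unordered pair of function classes; the rapid metabolizer (RM) category
exists only for CYP2C19 (one increased plus one normal allele). The
translation table must be total over the observed pairs — a missing pair
is a loud configuration error, not a default.

`phenotype_landscape` enumerates all diplotypes expressible over a table
(n(n+1)/2 unordered pairs at cn=2, plus multiplicity combinations up to
`max_cn`) with each cell scored independently.

## Guideline rules

Thirteen drug rules cover the tested drugs; aripiprazole and
brexpiprazole share one rule because their recommendations are
identical. Single-gene rules are actionable-phenotype sets (e.g.
citalopram/escitalopram: CYP2C19 {UM, RM, IM, PM}; pimozide: CYP2D6
{PM, IM}; quetiapine: CYP3A4 {PM}). The antipsychotic sets nest:
zuclopenthixol = haloperidol ∪ pimozide.

Sertraline (CYP2C19 × CYP2B6) and the five tricyclics (CYP2C19 ×
CYP2D6, one shared rule with aliases) use total recommendation matrices
over the non-Indeterminate phenotype domains. Each matrix cell is a
category label; actionability is a per-category flag, so classification
and recommendation cannot disagree by construction. `S` is standard
care everywhere; sertraline's `A` ("use caution / monitor") is
deliberately non-actionable while the TCA `A` (alternative drug) is
actionable. An `Indeterminate` phenotype at any required gene yields no
recommendation and is counted separately (excluded from actionable
numerators, retained in denominators).

## Population statistics

Per-drug actionable frequencies are compared with the pooled
two-proportion z-test without continuity correction, so z² equals the
uncorrected chi-square statistic of the 2×2 table exactly — a machine
precision identity the tests assert. The difference CI is Wald at 95%;
the odds ratio is the cross-product with a Woolf log-scale interval and
the Haldane–Anscombe 0.5 correction (flagged) when any cell is zero.
Degenerate tables (pooled proportion 0 or 1) return z=0, p=1 with a
flag. P-values are floored at the smallest positive double and never
reported as exactly zero. Benjamini–Hochberg adjustment runs across the
tested drugs (denominator overridable via `--m`); two significance
tiers are reported: BH-adjusted p < 0.05 and a genome-wide raw
threshold of 5×10⁻⁸.

Monte Carlo calibration (run in the test suite and acceptance script):
type-I error at α=0.05 lies in 0.05 ± 0.01 over 10,000 null replicates;
power for a 10-point gap at n=14,354 vs 2,504 exceeds 99% after BH. At
very small counts the normal approximation is compared against the
mid-p permutation null (half mass at the observed statistic), the
standard continuity-aware target for discrete references.

## Synthetic cohort generator

The simulator draws two haplotypes per sample per gene i.i.d. from a
profile's allele-frequency vector (Hardy–Weinberg equilibrium, i.e.
random mating, no inbreeding, no linkage between genes). CYP2D6
additionally receives per-haplotype deletion and duplication events at
profile-specified rates; a cn=1 sample presents its surviving haplotype
at homozygous-like dosage, exactly as the caller assumes. Output is a
VCF (written with pysam, carrying `##pgxBuild` and `##pgxSeed` headers),
a CN sidecar TSV and a truth TSV whose diplotype strings use the same
canonical formatter as the caller. All randomness flows from one
`numpy.random.default_rng(seed)`; identical inputs give byte-identical
files.

What it does **not** emulate: sequencing error, missing genotypes,
phasing errors, linkage disequilibrium between defining variants of
different alleles, population substructure, or rare/novel alleles
absent from the table. Recovery rates on simulated cohorts are
therefore upper bounds for real data.

The three built-in profiles are illustrative frequency mixtures chosen
so that the resulting phenotype and actionability distributions span
the ranges reported for Middle Eastern, global-reference and European
populations (e.g. `qgp_like` yields ≈57–59% citalopram/escitalopram
actionability and ≈45% sertraline actionability; `eu_like` ≈33–35%
sertraline). They are not measured population frequencies.

`profile_from_phenotype_targets` inverts target phenotype fractions to
haplotype frequencies by constrained least squares (SLSQP over the
simplex, multiple starts); infeasible targets raise an error reporting
the best achieved residual.

## Numerical and engineering conventions

- Seeds: a single user seed is split with `numpy.random.SeedSequence`;
  derived seeds stay below 2³¹.
- All percentages print at one decimal; machine-readable outputs keep
  full precision.
- Shipped data (star-allele table with 490 definitions across the four
  genes, phenotype configuration, drug rules, frequency profiles) are
  plain TSV/YAML under `src/pgxaction/data/` and round-trip through
  their loaders.
- The allele table uses synthetic contigs (`PGX_<gene>`) and a
  `synthetic-1` build tag; the caller refuses a VCF whose `##pgxBuild`
  header disagrees with the table's build.

## Limitations

- Genotype-level calling cannot resolve cis/trans configurations of
  overlapping allele definitions without phasing; such calls are
  flagged with ranked alternatives rather than resolved.
- CYP2D6 duplication assignment from a total copy number alone is
  genuinely ambiguous for heterozygotes; the policy default (`higher`)
  is a convention, and the flag must be consulted downstream.
- The Wald interval and Woolf interval are asymptotic; at very small
  counts the mid-p permutation comparison in the tests bounds the
  approximation error (≈8% relative at the probed configurations)
  rather than eliminating it.
- Guideline content is a simplified, self-consistent rule set for the
  thirteen tested drugs, not a substitute for the full CPIC/DPWG
  guideline text.
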