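"""Diplotype assignment from genotype-level variant calls.

Given a sample's genotypes restricted to the four gene regions, the caller
enumerates every unordered pair of star alleles whose combined defining
variants exactly reproduce the observed alternate-allele dosage, ranks ties
deterministically, and then reconciles the CYP2D6 call with an externally
supplied integer copy number (whole-gene deletion *5, duplications ``*1x2``).

This operates at genotype level: structural evidence arrives as a per-sample
copy-number sidecar rather than from read alignments, and hybrid CYP2D6-2D7
fusion alleles are out of scope.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from itertools import combinations_with_replacement
from pathlib import Path

import pysam

from .allele_registry import (
    DELETION_ALLELE,
    AlleleTable,
    AlleleTableError,
    VariantKey,
    alleles_compatible_with,
)

__all__ = [
    "Genotype",
    "SampleGenotypes",
    "DiplotypeCall",
    "CallError",
    "enumerate_diplotypes",
    "select_diplotype",
    "apply_copy_number",
    "call_sample",
    "call_cohort",
    "read_cn_sidecar",
    "calls_to_frame",
]

logger = logging.getLogger(__name__)

#: warn about a possible novel allele past this many unindexed variants
NOVEL_VARIANT_WARN_THRESHOLD = 5

FLAG_UNPHASED = "unphased_ambiguity"
FLAG_CN = "cn_ambiguity"
FLAG_NO_CALL = "no_call"


class CallError(ValueError):
    """Invalid caller input (bad copy number, sample mismatch, ...)."""


@dataclass(frozen=True)
class Genotype:
    """A diploid genotype at one site: allele indices restricted to {0, 1}."""

    a0: int
    a1: int
    phased: bool = False

    @property
    def dosage(self) -> int:
        return self.a0 + self.a1


@dataclass
class SampleGenotypes:
    """Per-gene genotype maps for one sample, plus its CYP2D6 copy number."""

    sample_id: str
    genotypes: dict[str, dict[VariantKey, Genotype]] = field(default_factory=dict)
    cyp2d6_copy_number: int = 2
    ignored_variant_counts: dict[str, int] = field(default_factory=dict)

    def gene_genotypes(self, gene: str) -> dict[VariantKey, Genotype]:
        return self.genotypes.get(gene, {})


@dataclass
class DiplotypeCall:
    """One gene's resolved diplotype with multiplicities and ambiguity set."""

    gene: str
    allele_a: str | None
    mult_a: int
    allele_b: str | None
    mult_b: int
    ambiguous_alternatives: list[str] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    @property
    def is_no_call(self) -> bool:
        return FLAG_NO_CALL in self.flags

    def alleles(self) -> list[tuple[str, int]]:
        out = []
        if self.allele_a is not None and self.mult_a > 0:
            out.append((self.allele_a, self.mult_a))
        if self.allele_b is not None and self.mult_b > 0:
            out.append((self.allele_b, self.mult_b))
        return out

    def __str__(self) -> str:
        if self.is_no_call:
            return "no_call"
        sides = [
            (name if name is not None and mult > 0 else DELETION_ALLELE, max(mult, 1))
            for name, mult in ((self.allele_a, self.mult_a), (self.allele_b, self.mult_b))
        ]
        return format_diplotype(sides)


def format_diplotype(sides: list[tuple[str, int]]) -> str:
    """Canonical diplotype string: numeric-aware name order, e.g. ``*1x2/*4``."""
    ordered = sorted(sides, key=lambda s: (_allele_sort_key(s[0]), -s[1]))
    return "/".join(n if m == 1 else f"{n}x{m}" for n, m in ordered)


def _pair_string(a: str, b: str) -> str:
    a, b = sorted((a, b), key=_allele_sort_key)
    return f"{a}/{b}"


def _allele_sort_key(name: str):
    # *2 before *10: numeric-aware ordering of star names
    core = name.lstrip("*")
    return (0, int(core)) if core.isdigit() else (1, core)


# ---------------------------------------------------------------------------
# candidate enumeration


def enumerate_diplotypes(
    genotypes: SampleGenotypes, gene: str, table: AlleleTable
) -> list[tuple[str, str]]:
    """All unordered allele pairs that exactly reproduce the observed dosage.

    A pair (h1, h2) is a candidate when the multiset union of its defining
    variants equals the sample's alternate-allele dosage at every indexed
    position (1 = het, 2 = hom). If every heterozygous genotype is phased,
    assignment is constrained to the stated haplotypes. The all-reference
    case always yields ``(*1, *1)``; dosage-inconsistent input yields an
    empty list (the caller then emits a no-call).
    """
    gts = genotypes.gene_genotypes(gene)
    observed = {v: gt for v, gt in gts.items() if gt.dosage > 0}
    dosage = Counter({v: gt.dosage for v, gt in observed.items()})

    compatible = alleles_compatible_with(table, gene, dosage.keys())

    het = [v for v, gt in observed.items() if gt.dosage == 1]
    fully_phased = bool(het) and all(observed[v].phased for v in het)
    if fully_phased:
        hap0 = frozenset(v for v, gt in observed.items() if gt.a0 == 1)
        hap1 = frozenset(v for v, gt in observed.items() if gt.a1 == 1)
        by_set: dict[frozenset[VariantKey], list[str]] = {}
        for d in compatible:
            by_set.setdefault(d.defining_variants, []).append(d.name)
        pairs = set()
        for n0 in by_set.get(hap0, []):
            for n1 in by_set.get(hap1, []):
                pairs.add(tuple(sorted((n0, n1), key=_allele_sort_key)))
        return sorted(pairs, key=lambda p: tuple(map(_allele_sort_key, p)))

    pairs = set()
    for d1, d2 in combinations_with_replacement(compatible, 2):
        combined = Counter()
        for v in d1.defining_variants:
            combined[v] += 1
        for v in d2.defining_variants:
            combined[v] += 1
        if combined == dosage:
            pairs.add(tuple(sorted((d1.name, d2.name), key=_allele_sort_key)))
    return sorted(pairs, key=lambda p: tuple(map(_allele_sort_key, p)))


def select_diplotype(
    candidates: list[tuple[str, str]], gene: str, table: AlleleTable
) -> DiplotypeCall:
    """Pick one diplotype from equally dosage-consistent candidates.

    Ranking: (1) most defining variants explained by named non-reference
    alleles, (2) fewest distinct non-reference alleles, (3) numeric-aware
    lexicographic allele order. With unphased input every unchosen candidate
    remains genuinely possible, so all alternatives are preserved and the
    ``unphased_ambiguity`` flag set whenever more than one candidate exists.
    """
    if not candidates:
        return DiplotypeCall(gene, None, 0, None, 0, flags={FLAG_NO_CALL})

    def rank(pair: tuple[str, str]):
        defs = [table.get(gene, n) for n in pair]
        explained = sum(len(d.defining_variants) for d in defs if not d.is_reference)
        distinct_nonref = len({d.name for d in defs if not d.is_reference})
        return (-explained, distinct_nonref, tuple(map(_allele_sort_key, pair)))

    ranked = sorted(candidates, key=rank)
    best = ranked[0]
    call = DiplotypeCall(gene, best[0], 1, best[1], 1)
    if len(ranked) > 1:
        call.flags.add(FLAG_UNPHASED)
        call.ambiguous_alternatives = [_pair_string(*p) for p in ranked[1:]]
    return call


# ---------------------------------------------------------------------------
# copy-number reconciliation (CYP2D6)


def apply_copy_number(
    call: DiplotypeCall, cn: int, table: AlleleTable, policy: str = "higher"
) -> DiplotypeCall:
    """Reconcile a diploid CYP2D6 call with an integer gene copy number.

    ``cn == 2`` leaves the call unchanged; ``cn == 1`` keeps one allele with
    a *5 (deletion) partner; ``cn == 0`` is *5/*5; ``cn > 2`` assigns the
    extra copies to one allele under the duplication ``policy`` — ``higher``
    (default) duplicates the higher-activity allele, ``lower`` the lower-
    activity one, ``ambiguous`` duplicates the higher one but records the
    alternative. Any heterozygous reassignment sets the ``cn_ambiguity`` flag.
    """
    if cn < 0:
        raise CallError(f"copy number must be >= 0, got {cn}")
    if call.gene != "CYP2D6":
        raise CallError("copy-number reconciliation applies to CYP2D6 only")
    if policy not in ("higher", "lower", "ambiguous"):
        raise CallError(f"unknown duplication policy {policy!r}")
    if call.is_no_call or cn == 2:
        return call

    out = replace(
        call,
        flags=set(call.flags),
        ambiguous_alternatives=list(call.ambiguous_alternatives),
    )
    if cn == 0:
        out.allele_a, out.mult_a = DELETION_ALLELE, 1
        out.allele_b, out.mult_b = DELETION_ALLELE, 1
        return out

    homozygous = call.allele_a == call.allele_b

    if cn == 1:
        # A true single-copy sample presents its surviving haplotype at hom
        # dosage, so the diploid call is homozygous; a het call here cannot be
        # resolved from genotypes alone.
        out.allele_b, out.mult_b = DELETION_ALLELE, 1
        out.mult_a = 1
        if not homozygous:
            out.flags.add(FLAG_CN)
            out.ambiguous_alternatives.append(f"{call.allele_b}/{DELETION_ALLELE}")
        return out

    # cn >= 3
    extra = cn - 2
    if homozygous:
        out.mult_a = 1 + extra
        out.mult_b = 1
        return out

    def activity(name: str) -> float:
        val = table.get("CYP2D6", name).activity_value
        return -1.0 if isinstance(val, str) else float(val)

    names = sorted([call.allele_a, call.allele_b], key=_allele_sort_key)
    by_activity = sorted(names, key=lambda n: (activity(n), _allele_sort_key(n)))
    target = by_activity[-1] if policy in ("higher", "ambiguous") else by_activity[0]
    other = names[0] if target == names[1] else names[1]
    out.allele_a, out.mult_a = target, 1 + extra
    out.allele_b, out.mult_b = other, 1
    out.flags.add(FLAG_CN)
    if policy == "ambiguous":
        out.ambiguous_alternatives.append(f"{other}x{1 + extra}/{target}")
    return out


# ---------------------------------------------------------------------------
# per-sample and cohort drivers


def call_sample(
    genotypes: SampleGenotypes, table: AlleleTable, duplication_policy: str = "higher"
) -> dict[str, DiplotypeCall]:
    """Diplotype every gene present in the table for one sample."""
    calls: dict[str, DiplotypeCall] = {}
    for gene in table.genes():
        candidates = enumerate_diplotypes(genotypes, gene, table)
        call = select_diplotype(candidates, gene, table)
        if gene == "CYP2D6" and not call.is_no_call:
            call = apply_copy_number(
                call, genotypes.cyp2d6_copy_number, table, policy=duplication_policy
            )
        calls[gene] = call
    return calls


def _genotype_from_record(sample_gt) -> Genotype | None:
    alleles = sample_gt.get("GT")
    if alleles is None or len(alleles) != 2 or any(a is None for a in alleles):
        return None
    a0, a1 = (1 if a >= 1 else 0 for a in alleles)
    return Genotype(a0, a1, phased=bool(sample_gt.phased))


def read_vcf_genotypes(vcf_path: str | Path, table: AlleleTable) -> list[SampleGenotypes]:
    """Load per-sample genotypes from a VCF, keeping only indexed variants.

    Variants absent from the allele index are dropped with a per-gene-region
    count; a sample exceeding :data:`NOVEL_VARIANT_WARN_THRESHOLD` dropped
    variants logs a possible-novel-allele warning.
    """
    try:
        vcf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise CallError(f"cannot read VCF {vcf_path}: {exc}") from exc

    vcf_build = None
    for rec in vcf.header.records:
        if rec.key == "pgxBuild":
            vcf_build = rec.value
    if vcf_build and vcf_build != table.build:
        raise CallError(
            f"genome build mismatch: VCF declares {vcf_build!r}, table is {table.build!r}"
        )

    samples = {
        s: SampleGenotypes(sample_id=s, genotypes={g: {} for g in table.genes()})
        for s in vcf.header.samples
    }
    ignored: dict[str, Counter] = {s: Counter() for s in samples}
    for record in vcf:
        for alt_index, alt in enumerate(record.alts or (), start=1):
            key = VariantKey(record.chrom, record.pos, record.ref, alt)
            gene = table.gene_of_variant(key)
            for sample_id, sample in samples.items():
                raw = record.samples[sample_id].get("GT")
                if raw is None or any(a is None for a in raw):
                    continue
                if gene is None:
                    if any(a == alt_index for a in raw):
                        ignored[sample_id][record.chrom] += 1
                    continue
                a0, a1 = (1 if a == alt_index else 0 for a in raw)
                if a0 + a1 == 0:
                    continue
                sample.genotypes[gene][key] = Genotype(
                    a0, a1, phased=bool(record.samples[sample_id].phased)
                )
    for sample_id, counts in ignored.items():
        samples[sample_id].ignored_variant_counts = dict(counts)
        for region, n in counts.items():
            if n > NOVEL_VARIANT_WARN_THRESHOLD:
                logger.warning(
                    "sample %s: %d variants in %s absent from the allele index "
                    "(possible novel allele)",
                    sample_id,
                    n,
                    region,
                )
    return list(samples.values())


def read_cn_sidecar(path: str | Path) -> dict[str, int]:
    """Read the CYP2D6 copy-number sidecar TSV (sample_id, gene, copy_number)."""
    out: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = {"sample_id", "gene", "copy_number"}
        if not required <= set(header):
            raise CallError(f"CN sidecar missing columns {sorted(required - set(header))}")
        idx = {c: header.index(c) for c in header}
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not line.strip():
                continue
            if fields[idx["gene"]] != "CYP2D6":
                continue
            cn = int(fields[idx["copy_number"]])
            if cn < 0:
                raise CallError(f"negative copy number for {fields[idx['sample_id']]}")
            out[fields[idx["sample_id"]]] = cn
    return out


def call_cohort(
    vcf_path: str | Path,
    table: AlleleTable,
    cn_sidecar: str | Path | None = None,
    duplication_policy: str = "higher",
) -> dict[str, dict[str, DiplotypeCall]]:
    """Diplotype every sample in a VCF; deterministic for identical inputs."""
    samples = read_vcf_genotypes(vcf_path, table)
    if not samples:
        logger.warning("VCF %s contains no samples", vcf_path)
    cn = read_cn_sidecar(cn_sidecar) if cn_sidecar else {}
    known = {s.sample_id for s in samples}
    unknown = set(cn) - known
    if unknown:
        raise CallError(f"CN sidecar samples absent from VCF: {sorted(unknown)}")
    results: dict[str, dict[str, DiplotypeCall]] = {}
    n_no_call = n_ambiguous = 0
    for sample in samples:
        sample.cyp2d6_copy_number = cn.get(sample.sample_id, 2)
        calls = call_sample(sample, table, duplication_policy=duplication_policy)
        n_no_call += sum(c.is_no_call for c in calls.values())
        n_ambiguous += sum(bool(c.ambiguous_alternatives) for c in calls.values())
        results[sample.sample_id] = calls
    logger.info(
        "called %d samples: %d no-calls, %d ambiguous gene calls",
        len(results),
        n_no_call,
        n_ambiguous,
    )
    return results


def calls_to_frame(calls: dict[str, dict[str, DiplotypeCall]]):
    """Flatten cohort calls to a tidy table (one row per sample per gene)."""
    import pandas as pd

    rows = []
    for sample_id in sorted(calls):
        for gene, call in calls[sample_id].items():
            rows.append(
                {
                    "sample_id": sample_id,
                    "gene": gene,
                    "diplotype": str(call),
                    "flags": ",".join(sorted(call.flags)),
                    "alternatives": ",".join(call.ambiguous_alternatives),
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "gene", "diplotype", "flags", "alternatives"])
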