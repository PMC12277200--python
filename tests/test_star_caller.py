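"""Diplotype enumeration, tie-breaking, copy-number handling, cohort calling."""

from collections import Counter
from itertools import combinations_with_replacement

import pytest

from pgxaction.allele_registry import AlleleTable, VariantKey
from pgxaction.phenotyper import default_phenotype_config, phenotype_cohort
from pgxaction.star_caller import (
    FLAG_CN,
    FLAG_UNPHASED,
    CallError,
    DiplotypeCall,
    Genotype,
    SampleGenotypes,
    apply_copy_number,
    call_cohort,
    enumerate_diplotypes,
    select_diplotype,
)
from pgxaction.synthetic_data import builtin_profile, simulate_cohort

from conftest import make_allele


def sample_with(gene, table, genotype_map, sample_id="S1", cn=2):
    """Build SampleGenotypes from {allele_name: dosage} against a table."""
    gts = {}
    for name, dosage in genotype_map.items():
        for v in table.get(gene, name).defining_variants:
            gts[v] = Genotype(1 if dosage >= 1 else 0, 1 if dosage == 2 else 0)
    return SampleGenotypes(sample_id, {gene: gts}, cyp2d6_copy_number=cn)


def brute_force_pairs(genotypes, gene, table):
    """Independent O(A^2) oracle over every allele pair in the table."""
    dosage = Counter(
        {v: gt.dosage for v, gt in genotypes.gene_genotypes(gene).items() if gt.dosage > 0}
    )
    alleles = [d for d in table.alleles(gene) if not d.is_deletion]
    out = set()
    for d1, d2 in combinations_with_replacement(alleles, 2):
        combined = Counter()
        for v in list(d1.defining_variants) + list(d2.defining_variants):
            combined[v] += 1
        if combined == dosage:
            out.add(frozenset(Counter([d1.name, d2.name]).items()))
    return out


def as_sets(pairs):
    return {frozenset(Counter(p).items()) for p in pairs}


class TestEnumeration:
    def test_all_reference_gives_star1_homozygote(self, mini_d6_table):
        s = sample_with("CYP2D6", mini_d6_table, {})
        assert enumerate_diplotypes(s, "CYP2D6", mini_d6_table) == [("*1", "*1")]

    def test_hom_alt_forces_homozygote(self, mini_d6_table):
        s = sample_with("CYP2D6", mini_d6_table, {"*4": 2})
        assert enumerate_diplotypes(s, "CYP2D6", mini_d6_table) == [("*4", "*4")]

    def test_het_het_candidates_match_oracle(self, overlap_d6_table):
        s = sample_with("CYP2D6", overlap_d6_table, {"*4": 1, "*10": 1})
        got = enumerate_diplotypes(s, "CYP2D6", overlap_d6_table)
        assert as_sets(got) == brute_force_pairs(s, "CYP2D6", overlap_d6_table)
        assert as_sets(got) == {
            frozenset([("*4", 1), ("*10", 1)]),
            frozenset([("*1", 1), ("*36", 1)]),
        }

    def test_oracle_equivalence_on_fixture_subtables(self, full_table):
        """Candidate sets equal the exhaustive pair oracle on <=20-allele tables."""
        for gene in full_table.genes():
            sub = AlleleTable(
                definitions={gene: full_table.alleles(gene)[:20]}, build=full_table.build
            )
            alleles = [d for d in sub.alleles(gene) if not d.is_deletion]
            # probe with the genotypes of every true diplotype of the first 6 alleles
            for d1, d2 in combinations_with_replacement(alleles[:6], 2):
                dosage = Counter()
                for v in list(d1.defining_variants) + list(d2.defining_variants):
                    dosage[v] += 1
                gts = {v: Genotype(1, 1 if c == 2 else 0) for v, c in dosage.items()}
                s = SampleGenotypes("S1", {gene: gts})
                got = as_sets(enumerate_diplotypes(s, gene, sub))
                assert got == brute_force_pairs(s, gene, sub)
                assert frozenset(Counter([d1.name, d2.name]).items()) in got

    def test_dosage_inconsistent_input_yields_empty(self, mini_d6_table):
        # hom *4 variant plus het *10 variant: no pair reproduces dosage 3
        v4 = next(iter(mini_d6_table.get("CYP2D6", "*4").defining_variants))
        v10 = next(iter(mini_d6_table.get("CYP2D6", "*10").defining_variants))
        s = SampleGenotypes(
            "S1", {"CYP2D6": {v4: Genotype(1, 1), v10: Genotype(0, 1)}}
        )
        assert enumerate_diplotypes(s, "CYP2D6", mini_d6_table) == []

    def test_phase_constrains_assignment(self, overlap_d6_table):
        """Phased *4|*10 excludes the (*1, *36) explanation."""
        v4 = next(iter(overlap_d6_table.get("CYP2D6", "*4").defining_variants))
        v10 = next(iter(overlap_d6_table.get("CYP2D6", "*10").defining_variants))
        s = SampleGenotypes(
            "S1",
            {"CYP2D6": {v4: Genotype(1, 0, phased=True), v10: Genotype(0, 1, phased=True)}},
        )
        assert enumerate_diplotypes(s, "CYP2D6", overlap_d6_table) == [("*4", "*10")]
        cis = SampleGenotypes(
            "S1",
            {"CYP2D6": {v4: Genotype(1, 0, phased=True), v10: Genotype(1, 0, phased=True)}},
        )
        assert enumerate_diplotypes(cis, "CYP2D6", overlap_d6_table) == [("*1", "*36")]

    def test_dosage_conservation(self, overlap_d6_table):
        s = sample_with("CYP2D6", overlap_d6_table, {"*4": 1, "*10": 1})
        dosage = Counter(
            {v: gt.dosage for v, gt in s.gene_genotypes("CYP2D6").items() if gt.dosage}
        )
        for pair in enumerate_diplotypes(s, "CYP2D6", overlap_d6_table):
            combined = Counter()
            for name in pair:
                for v in overlap_d6_table.get("CYP2D6", name).defining_variants:
                    combined[v] += 1
            assert combined == dosage


class TestSelection:
    def test_single_candidate_no_flags(self, mini_d6_table):
        call = select_diplotype([("*1", "*4")], "CYP2D6", mini_d6_table)
        assert str(call) == "*1/*4"
        assert not call.flags

    def test_fewest_nonreference_preferred(self, overlap_d6_table):
        """(*1, *36) and (*4, *10) both explain everything; the former wins."""
        call = select_diplotype([("*1", "*36"), ("*4", "*10")], "CYP2D6", overlap_d6_table)
        assert str(call) == "*1/*36"
        assert call.flags == {FLAG_UNPHASED}
        assert call.ambiguous_alternatives == ["*4/*10"]

    def test_empty_candidates_is_no_call(self, mini_d6_table):
        call = select_diplotype([], "CYP2D6", mini_d6_table)
        assert call.is_no_call
        assert call.allele_a is None and call.allele_b is None


class TestCopyNumber:
    def test_diploid_identity(self, mini_d6_table):
        call = DiplotypeCall("CYP2D6", "*1", 1, "*4", 1)
        assert apply_copy_number(call, 2, mini_d6_table) is call

    def test_homozygous_triplication_unambiguous(self, mini_d6_table):
        call = DiplotypeCall("CYP2D6", "*1", 1, "*1", 1)
        out = apply_copy_number(call, 3, mini_d6_table)
        assert str(out) == "*1x2/*1"
        assert FLAG_CN not in out.flags

    @pytest.mark.parametrize(
        "policy, expected", [("higher", "*1x2/*4"), ("lower", "*1/*4x2")]
    )
    def test_heterozygous_duplication_policy(self, mini_d6_table, policy, expected):
        call = DiplotypeCall("CYP2D6", "*1", 1, "*4", 1)
        out = apply_copy_number(call, 3, mini_d6_table, policy=policy)
        assert str(out) == expected
        assert FLAG_CN in out.flags

    def test_deletion_states(self, mini_d6_table):
        hom = DiplotypeCall("CYP2D6", "*4", 1, "*4", 1)
        assert str(apply_copy_number(hom, 1, mini_d6_table)) == "*4/*5"
        ref = DiplotypeCall("CYP2D6", "*1", 1, "*1", 1)
        assert str(apply_copy_number(ref, 0, mini_d6_table)) == "*5/*5"

    def test_negative_cn_rejected(self, mini_d6_table):
        with pytest.raises(CallError, match=">= 0"):
            apply_copy_number(DiplotypeCall("CYP2D6", "*1", 1, "*1", 1), -1, mini_d6_table)

    def test_high_cn_multiplicity_arithmetic(self, mini_d6_table):
        call = DiplotypeCall("CYP2D6", "*1", 1, "*4", 1)
        out = apply_copy_number(call, 5, mini_d6_table)
        assert out.mult_a + out.mult_b == 5


class TestCohort:
    def test_exact_recovery_on_separable_cohort(self, full_table, tmp_path):
        """No CN events + disjoint definitions: every diplotype recovered."""
        profile = builtin_profile("qgp_like")
        profile.cyp2d6_deletion_rate = 0.0
        profile.cyp2d6_duplication_rate = 0.0
        cohort = simulate_cohort(profile, 500, 20240101, full_table, tmp_path)
        calls = call_cohort(cohort.vcf_path, full_table, cn_sidecar=cohort.cn_path)
        frame = phenotype_cohort(calls, full_table, default_phenotype_config())
        merged = frame.merge(
            cohort.truth, on=["sample_id", "gene"], suffixes=("_call", "_true")
        )
        assert len(merged) == 500 * 4
        assert (merged["diplotype_call"] == merged["diplotype_true"]).all()

    def test_cohort_calls_are_deterministic(self, full_table, tmp_path):
        profile = builtin_profile("eu_like")
        cohort = simulate_cohort(profile, 30, 7, full_table, tmp_path)
        a = call_cohort(cohort.vcf_path, full_table, cn_sidecar=cohort.cn_path)
        b = call_cohort(cohort.vcf_path, full_table, cn_sidecar=cohort.cn_path)
        assert {s: {g: str(c) for g, c in v.items()} for s, v in a.items()} == {
            s: {g: str(c) for g, c in v.items()} for s, v in b.items()
        }

    def test_cn_sidecar_sample_mismatch_rejected(self, full_table, tmp_path):
        cohort = simulate_cohort(builtin_profile("qgp_like"), 3, 1, full_table, tmp_path)
        bad = tmp_path / "bad_cn.tsv"
        bad.write_text("sample_id\tgene\tcopy_number\nGHOST\tCYP2D6\t2\n")
        with pytest.raises(CallError, match="GHOST"):
            call_cohort(cohort.vcf_path, full_table, cn_sidecar=bad)

    def test_header_only_vcf_yields_empty_call_set(self, full_table, tmp_path):
        vcf = tmp_path / "empty.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        assert call_cohort(vcf, full_table) == {}

    def test_build_mismatch_refused(self, full_table, tmp_path):
        vcf = tmp_path / "wrong_build.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##pgxBuild=other-build\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        )
        with pytest.raises(CallError, match="build mismatch"):
            call_cohort(vcf, full_table)
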