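"""Synthetic cohort generation with known truth.

Cohorts are drawn under Hardy–Weinberg equilibrium: two haplotypes per gene
per sample, i.i.d. from a configurable star-allele frequency profile, with
CYP2D6 copy-number events (whole-gene deletion *5, single-gene duplication)
applied per haplotype at configured rates. The generator writes a genotype
VCF on miniature synthetic contigs, a CYP2D6 copy-number sidecar TSV, and a
truth table whose phenotypes are produced by the package's own phenotyper —
so every downstream stage can be tested end to end without any
access-controlled cohort data.

A hemizygous sample (one deleted haplotype) presents its surviving
haplotype's variants at homozygous dosage, as a diploid genotype caller
would report them; duplicated haplotypes keep diploid genotypes, with the
extra copy visible only through the sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml
from scipy import optimize

from .allele_registry import DELETION_ALLELE, AlleleTable, VariantKey
from .phenotyper import PhenotypeConfig, phenotype_call
from .star_caller import DiplotypeCall, format_diplotype

__all__ = [
    "FrequencyProfile",
    "SimulatedCohort",
    "ProfileError",
    "load_profile",
    "builtin_profile",
    "BUILTIN_PROFILES",
    "simulate_cohort",
    "profile_from_phenotype_targets",
]

BUILTIN_PROFILES = ("qgp_like", "onekg_like", "eu_like")

_FREQ_TOL = 1e-9


class ProfileError(ValueError):
    """Invalid frequency profile."""


@dataclass
class FrequencyProfile:
    """Per-gene star-allele haplotype frequencies plus CYP2D6 CN event rates."""

    label: str
    frequencies: dict[str, dict[str, float]]
    cyp2d6_deletion_rate: float = 0.0
    cyp2d6_duplication_rate: float = 0.0

    def __post_init__(self) -> None:
        for gene, freqs in self.frequencies.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > _FREQ_TOL:
                raise ProfileError(f"{self.label}/{gene}: frequencies sum to {total}, not 1")
            if any(f < 0 or f > 1 for f in freqs.values()):
                raise ProfileError(f"{self.label}/{gene}: frequency outside [0, 1]")
        for rate in (self.cyp2d6_deletion_rate, self.cyp2d6_duplication_rate):
            if not 0.0 <= rate <= 1.0:
                raise ProfileError(f"{self.label}: CN rate {rate} outside [0, 1]")
        if self.cyp2d6_deletion_rate + self.cyp2d6_duplication_rate > 1.0:
            raise ProfileError(f"{self.label}: CN event rates exceed 1 combined")


def load_profile(path: str | Path) -> FrequencyProfile:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cn = raw.get("cyp2d6_cn", {})
    return FrequencyProfile(
        label=str(raw["label"]),
        frequencies={g: {a: float(f) for a, f in m.items()} for g, m in raw["genes"].items()},
        cyp2d6_deletion_rate=float(cn.get("deletion", 0.0)),
        cyp2d6_duplication_rate=float(cn.get("duplication", 0.0)),
    )


def builtin_profile(name: str) -> FrequencyProfile:
    """One of the shipped illustrative profiles (qgp_like, onekg_like, eu_like)."""
    if name not in BUILTIN_PROFILES:
        raise ProfileError(f"unknown builtin profile {name!r} (have {BUILTIN_PROFILES})")
    return load_profile(str(resources.files("pgxaction").joinpath(f"data/profiles/{name}.yaml")))


@dataclass
class SimulatedCohort:
    """Simulation output bundle: file paths plus in-memory truth."""

    vcf_path: Path
    cn_path: Path
    truth_path: Path
    truth: pd.DataFrame  # sample_id, gene, diplotype, phenotype, copy_number
    seed: int

    def truth_phenotypes(self) -> pd.DataFrame:
        return self.truth[["sample_id", "gene", "phenotype"]].copy()


def simulate_cohort(
    profile: FrequencyProfile,
    n: int,
    seed: int,
    table: AlleleTable,
    out_dir: str | Path,
    phenotype_config: PhenotypeConfig | None = None,
    phased: bool = False,
    prefix: str = "cohort",
) -> SimulatedCohort:
    """Draw ``n`` samples under HWE and write VCF + CN sidecar + truth TSV.

    Deterministic for a fixed seed (the seed is recorded in the VCF header).
    Truth phenotypes are computed with the package phenotyper on the truth
    diplotypes, so truth is self-consistent by construction.
    """
    if n < 1:
        raise ProfileError("cohort size must be >= 1")
    from .phenotyper import default_phenotype_config

    config = phenotype_config or default_phenotype_config()
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sample_ids = [f"S{i:05d}" for i in range(1, n + 1)]

    genes = [g for g in table.genes() if g in profile.frequencies]
    if not genes:
        raise ProfileError("profile covers no gene present in the allele table")

    # draw haplotypes gene by gene
    haplotypes: dict[str, np.ndarray] = {}  # gene -> (n, 2) allele-name indices
    allele_names: dict[str, list[str]] = {}
    for gene in genes:
        freqs = profile.frequencies[gene]
        names = sorted(freqs)
        for name in names:
            table.get(gene, name)  # existence check
        probs = np.array([freqs[a] for a in names])
        probs = probs / probs.sum()
        haplotypes[gene] = rng.choice(len(names), size=(n, 2), p=probs)
        allele_names[gene] = names

    # CYP2D6 copy-number events per haplotype: 0 = none, 1 = deletion, 2 = duplication
    cn_events = np.zeros((n, 2), dtype=int)
    if "CYP2D6" in genes:
        u = rng.random((n, 2))
        cn_events[u < profile.cyp2d6_deletion_rate] = 1
        both = profile.cyp2d6_deletion_rate + profile.cyp2d6_duplication_rate
        cn_events[(u >= profile.cyp2d6_deletion_rate) & (u < both)] = 2

    # per-sample truth and genotype assembly
    truth_rows = []
    copy_numbers = np.full(n, 2, dtype=int)
    hap_variant_sets: dict[str, list[tuple[set, set]]] = {g: [] for g in genes}
    for i in range(n):
        for gene in genes:
            names = allele_names[gene]
            a0 = names[haplotypes[gene][i, 0]]
            a1 = names[haplotypes[gene][i, 1]]
            pairs: list[tuple[str, int]]
            if gene == "CYP2D6":
                ev0, ev1 = cn_events[i]
                cn = (0 if ev0 == 1 else 2 if ev0 == 2 else 1) + (
                    0 if ev1 == 1 else 2 if ev1 == 2 else 1
                )
                copy_numbers[i] = cn
                sides = []
                for name, ev in ((a0, ev0), (a1, ev1)):
                    if ev == 1:
                        sides.append((DELETION_ALLELE, 1))
                    else:
                        sides.append((name, 2 if ev == 2 else 1))
                pairs = sides
                v0 = set() if ev0 == 1 else set(table.get(gene, a0).defining_variants)
                v1 = set() if ev1 == 1 else set(table.get(gene, a1).defining_variants)
                # hemizygous survivor presents at hom dosage
                if ev0 == 1 and ev1 != 1:
                    v0 = set(v1)
                if ev1 == 1 and ev0 != 1:
                    v1 = set(v0)
            else:
                pairs = [(a0, 1), (a1, 1)]
                v0 = set(table.get(gene, a0).defining_variants)
                v1 = set(table.get(gene, a1).defining_variants)
            hap_variant_sets[gene].append((v0, v1))
            (na, ma), (nb, mb) = pairs
            call = DiplotypeCall(gene, na, ma, nb, mb)
            truth_rows.append(
                {
                    "sample_id": sample_ids[i],
                    "gene": gene,
                    "diplotype": format_diplotype(pairs),
                    "phenotype": phenotype_call(call, table, config),
                    "copy_number": copy_numbers[i] if gene == "CYP2D6" else 2,
                }
            )
    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "gene", "diplotype", "phenotype", "copy_number"]
    )

    # variant sites: union of defining variants of profiled alleles
    sites: list[tuple[str, VariantKey]] = []
    for gene in genes:
        seen: set[VariantKey] = set()
        for name in allele_names[gene]:
            for v in table.get(gene, name).defining_variants:
                if v not in seen:
                    seen.add(v)
                    sites.append((gene, v))
    sites.sort(key=lambda gv: (gv[1].chrom, gv[1].pos, gv[1].ref, gv[1].alt))

    vcf_path = out_dir / f"{prefix}.vcf"
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    for contig in sorted({v.chrom for _, v in sites}) or ["PGX_EMPTY"]:
        header.add_line(f"##contig=<ID={contig},length=100000>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(f"##pgxBuild={table.build}")
    header.add_line(f"##pgxSeed={seed}")
    for s in sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vcf:
        for gene, v in sites:
            record = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt), id=None
            )
            record.qual = None
            sets = hap_variant_sets[gene]
            for i, s in enumerate(sample_ids):
                g0 = 1 if v in sets[i][0] else 0
                g1 = 1 if v in sets[i][1] else 0
                record.samples[s]["GT"] = (g0, g1)
                record.samples[s].phased = phased
            vcf.write(record)

    cn_path = out_dir / f"{prefix}.cn.tsv"
    with open(cn_path, "w") as fh:
        fh.write("sample_id\tgene\tcopy_number\n")
        if "CYP2D6" in genes:
            for i, s in enumerate(sample_ids):
                fh.write(f"{s}\tCYP2D6\t{copy_numbers[i]}\n")

    truth_path = out_dir / f"{prefix}.truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return SimulatedCohort(vcf_path, cn_path, truth_path, truth, seed)


# ---------------------------------------------------------------------------
# calibration: phenotype targets -> haplotype frequencies


def profile_from_phenotype_targets(
    targets: dict[str, dict[str, float]],
    table: AlleleTable,
    phenotype_config: PhenotypeConfig | None = None,
    label: str = "fitted",
    tol: float = 1e-3,
) -> tuple[FrequencyProfile, float]:
    """Fit haplotype-class frequencies whose HWE mixture matches phenotype goals.

    For each targeted gene, one representative allele per available function
    class is taken from the table and the class frequencies are fit by
    constrained least squares so the HWE diplotype mixture reproduces the
    target phenotype frequencies. Returns the profile and the worst per-gene
    residual (root-mean-square over targeted phenotypes); a residual above
    ``tol`` raises with the best residual reported.
    """
    from .phenotyper import default_phenotype_config

    config = phenotype_config or default_phenotype_config()
    frequencies: dict[str, dict[str, float]] = {}
    worst = 0.0
    for gene, goal in targets.items():
        reps: list = []
        seen_classes: set[str] = set()
        for d in table.alleles(gene):
            if d.function_class == "uncertain" or d.is_deletion:
                continue
            if d.function_class not in seen_classes:
                seen_classes.add(d.function_class)
                reps.append(d)
        if not reps:
            raise ProfileError(f"{gene}: no usable function classes in table")
        k = len(reps)
        # phenotype of every representative pair
        pheno = {}
        for i in range(k):
            for j in range(k):
                call = DiplotypeCall(gene, reps[i].name, 1, reps[j].name, 1)
                pheno[(i, j)] = phenotype_call(call, table, config)

        def mixture(freqs: np.ndarray) -> dict[str, float]:
            out: dict[str, float] = {}
            for (i, j), ph in pheno.items():
                out[ph] = out.get(ph, 0.0) + freqs[i] * freqs[j]
            return out

        def objective(freqs: np.ndarray) -> float:
            mix = mixture(freqs)
            return sum((mix.get(ph, 0.0) - f) ** 2 for ph, f in goal.items())

        best = None
        for start in range(5):
            x0 = np.full(k, 1.0 / k) if start == 0 else np.random.default_rng(start).dirichlet(
                np.ones(k)
            )
            res = optimize.minimize(
                objective,
                x0,
                method="SLSQP",
                bounds=[(0.0, 1.0)] * k,
                constraints=[{"type": "eq", "fun": lambda f: f.sum() - 1.0}],
                options={"maxiter": 500, "ftol": 1e-14},
            )
            if best is None or res.fun < best.fun:
                best = res
        freqs = np.clip(best.x, 0.0, 1.0)
        freqs = freqs / freqs.sum()
        residual = float(np.sqrt(best.fun / max(len(goal), 1)))
        worst = max(worst, residual)
        if residual > tol:
            raise ProfileError(
                f"{gene}: targets {goal} not achievable under HWE with classes "
                f"{sorted(seen_classes)}; best residual {residual:.4g}"
            )
        frequencies[gene] = {reps[i].name: float(freqs[i]) for i in range(k) if freqs[i] > 0}
        # renormalize after dropping zeros
        total = sum(frequencies[gene].values())
        frequencies[gene] = {a: f / total for a, f in frequencies[gene].items()}
    return FrequencyProfile(label=label, frequencies=frequencies), worst
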