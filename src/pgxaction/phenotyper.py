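"""Diplotype → metabolizer-phenotype translation.

CYP2D6 phenotypes come from the activity score (AS): the copy-multiplicity-
weighted sum of curated per-allele activity values, binned into
PM (AS = 0), IM (0 < AS ≤ 1), NM (1 < AS ≤ 2.25) and UM (AS > 2.25) under the
2019 consensus convention. The boundary AS = 1.0 falls in IM, so *1/*5 and
*1/*4 are intermediate metabolizers. CYP2C19, CYP2B6 and CYP3A4 use
categorical translation of the unordered pair of allele function classes;
RM (rapid) exists only for CYP2C19. Both bin boundaries and categorical
rules are configuration, not code, because consortium conventions have been
revised historically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .allele_registry import AlleleTable
from .star_caller import DiplotypeCall

__all__ = [
    "PHENOTYPES",
    "PHENOTYPE_ORDER",
    "PhenotypeConfig",
    "PhenotypeConfigError",
    "load_phenotype_config",
    "default_phenotype_config",
    "cyp2d6_activity_score",
    "score_to_phenotype",
    "categorical_phenotype",
    "phenotype_call",
    "phenotype_cohort",
    "phenotype_landscape",
]

PHENOTYPES = ("UM", "RM", "NM", "IM", "PM", "Indeterminate")

#: severity ordering used by the monotonicity property (Indeterminate and RM
#: are not part of the activity-score scale)
PHENOTYPE_ORDER = {"PM": 0, "IM": 1, "NM": 2, "UM": 3}

UNCERTAIN = "uncertain"
INDETERMINATE = "Indeterminate"


class PhenotypeConfigError(ValueError):
    """Invalid or non-total phenotype translation configuration."""


@dataclass(frozen=True)
class ScoreBin:
    upper: float
    phenotype: str


@dataclass
class PhenotypeConfig:
    """CYP2D6 activity-score bins plus per-gene categorical pair rules."""

    cyp2d6_bins: list[ScoreBin]
    categorical: dict[str, dict[frozenset[str] | tuple[str, str], str]]

    def __post_init__(self) -> None:
        if not self.cyp2d6_bins:
            raise PhenotypeConfigError("no CYP2D6 bins configured")
        uppers = [b.upper for b in self.cyp2d6_bins]
        if uppers != sorted(uppers) or len(set(uppers)) != len(uppers):
            raise PhenotypeConfigError("CYP2D6 bins must have strictly increasing uppers")
        if uppers[0] != 0.0:
            raise PhenotypeConfigError("first CYP2D6 bin must cover exactly score 0")
        if not math.isinf(uppers[-1]):
            raise PhenotypeConfigError("last CYP2D6 bin must be unbounded")
        for b in self.cyp2d6_bins:
            if b.phenotype not in PHENOTYPES:
                raise PhenotypeConfigError(f"unknown phenotype {b.phenotype!r} in bins")
        for gene, rules in self.categorical.items():
            for pair, pheno in rules.items():
                if pheno not in PHENOTYPES:
                    raise PhenotypeConfigError(f"{gene}: unknown phenotype {pheno!r}")
                if pheno == "RM" and gene != "CYP2C19":
                    raise PhenotypeConfigError("RM is reserved for CYP2C19")


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b)))  # type: ignore[return-value]


def load_phenotype_config(path: str | Path) -> PhenotypeConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    bins = [ScoreBin(float(b["upper"]), str(b["phenotype"])) for b in raw["cyp2d6_bins"]]
    categorical: dict[str, dict[tuple[str, str], str]] = {}
    for gene, rules in raw.get("categorical", {}).items():
        parsed = {}
        for key, pheno in rules.items():
            a, _, b = key.partition("|")
            parsed[_pair_key(a, b)] = str(pheno)
        categorical[gene] = parsed
    return PhenotypeConfig(cyp2d6_bins=bins, categorical=categorical)


def default_phenotype_config() -> PhenotypeConfig:
    return load_phenotype_config(
        str(resources.files("pgxaction").joinpath("data/phenotype_config.yaml"))
    )


# ---------------------------------------------------------------------------
# CYP2D6 activity-score arithmetic


def cyp2d6_activity_score(call: DiplotypeCall, table: AlleleTable) -> float | str:
    """Multiplicity-weighted sum of allele activity values; *5 contributes 0.

    Returns ``"uncertain"`` when any contributing allele has uncertain
    function, mirroring the downstream Indeterminate phenotype.
    """
    if call.gene != "CYP2D6":
        raise ValueError("activity scores apply to CYP2D6 only")
    if call.is_no_call:
        raise ValueError("cannot score a no-call")
    total = 0.0
    for name, mult in call.alleles():
        definition = table.get("CYP2D6", name)
        if definition.function_class == UNCERTAIN or isinstance(definition.activity_value, str):
            return UNCERTAIN
        total += float(definition.activity_value) * mult
    return total


def score_to_phenotype(score: float | str, config: PhenotypeConfig) -> str:
    """Bin an activity score; bins are total over [0, ∞)."""
    if isinstance(score, str):
        return INDETERMINATE
    if score < 0:
        raise ValueError(f"negative activity score {score}")
    for b in config.cyp2d6_bins:
        if score <= b.upper:
            return b.phenotype
    raise AssertionError("unreachable: last bin is unbounded")


# ---------------------------------------------------------------------------
# categorical translation (CYP2C19, CYP2B6, CYP3A4)


def categorical_phenotype(
    gene: str, call: DiplotypeCall, table: AlleleTable, config: PhenotypeConfig
) -> str:
    """Translate the unordered function-class pair through the gene's rules.

    A missing pair is a configuration error, never a silent fallback; any
    uncertain-function allele yields Indeterminate.
    """
    if gene == "CYP2D6":
        raise ValueError("CYP2D6 uses activity-score binning, not categorical rules")
    if call.is_no_call:
        return INDETERMINATE
    classes = []
    for name, mult in call.alleles():
        classes.extend([table.get(gene, name).function_class] * mult)
    if len(classes) != 2:
        raise ValueError(f"{gene}: expected a diploid call, got {call}")
    if UNCERTAIN in classes:
        return INDETERMINATE
    rules = config.categorical.get(gene)
    if rules is None:
        raise PhenotypeConfigError(f"no categorical rules for {gene}")
    key = _pair_key(*classes)
    if key not in rules:
        raise PhenotypeConfigError(f"{gene}: no rule for function-class pair {key}")
    return rules[key]


def phenotype_call(call: DiplotypeCall, table: AlleleTable, config: PhenotypeConfig) -> str:
    """Phenotype one gene call, dispatching on the gene's translation mode."""
    if call.is_no_call:
        return INDETERMINATE
    if call.gene == "CYP2D6":
        return score_to_phenotype(cyp2d6_activity_score(call, table), config)
    return categorical_phenotype(call.gene, call, table, config)


def phenotype_cohort(calls, table: AlleleTable, config: PhenotypeConfig):
    """Phenotype a whole cohort of diplotype calls.

    Returns a tidy DataFrame with one row per sample per gene, including the
    CYP2D6 activity score where defined.
    """
    import pandas as pd

    rows = []
    for sample_id in sorted(calls):
        for gene, call in calls[sample_id].items():
            score = ""
            if gene == "CYP2D6" and not call.is_no_call:
                value = cyp2d6_activity_score(call, table)
                score = value if isinstance(value, str) else format(value, "g")
            rows.append(
                {
                    "sample_id": sample_id,
                    "gene": gene,
                    "diplotype": str(call),
                    "activity_score": score,
                    "phenotype": phenotype_call(call, table, config),
                }
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "gene", "diplotype", "activity_score", "phenotype"]
    )


# ---------------------------------------------------------------------------
# landscape enumeration


def phenotype_landscape(
    table: AlleleTable,
    config: PhenotypeConfig,
    gene: str = "CYP2D6",
    max_cn: int = 2,
):
    """Exhaustively enumerate diplotype combinations and their phenotypes.

    For total copy number 2 this is every unordered allele pair
    (n(n+1)/2 combinations for n alleles); higher ``max_cn`` adds the
    multiplicity-bearing combinations (a×(c-1), b) for each extra copy
    number c. Returns a DataFrame (diplotype, activity_score, phenotype).
    """
    if max_cn < 2:
        raise ValueError("max_cn must be >= 2")
    import pandas as pd

    alleles = sorted((d.name for d in table.alleles(gene)), key=lambda n: n.lstrip("*").zfill(6))
    rows = []
    seen: set[tuple[tuple[str, int], ...]] = set()
    for cn in range(2, max_cn + 1):
        for i, a in enumerate(alleles):
            for b in alleles[i:]:
                if cn == 2:
                    combos = [((a, 1), (b, 1))]
                else:
                    combos = [((a, cn - 1), (b, 1)), ((a, 1), (b, cn - 1))]
                for (na, ma), (nb, mb) in combos:
                    key = tuple(sorted(((na, ma), (nb, mb))))
                    if key in seen:
                        continue
                    seen.add(key)
                    call = DiplotypeCall(gene, na, ma, nb, mb)
                    if gene == "CYP2D6":
                        score = cyp2d6_activity_score(call, table)
                        pheno = score_to_phenotype(score, config)
                        score_text = score if isinstance(score, str) else format(score, "g")
                    else:
                        pheno = categorical_phenotype(gene, call, table, config)
                        score_text = ""
                    rows.append(
                        {"diplotype": str(call), "activity_score": score_text, "phenotype": pheno}
                    )
    return pd.DataFrame(rows, columns=["diplotype", "activity_score", "phenotype"])
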