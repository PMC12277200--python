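"""Per-drug clinical actionability and combined-gene recommendations.

Single-gene drugs (e.g. citalopram on CYP2C19, quetiapine on CYP3A4) are
classified by membership of the sample's metabolizer phenotype in the drug's
actionable set. Two-gene drugs — sertraline (CYP2C19×CYP2B6) and the shared
tricyclic-antidepressant rule (CYP2C19×CYP2D6) — use a total recommendation
matrix over phenotype pairs whose cells name lettered categories; a cell is
actionable exactly when its category is not standard care, so the matrix and
the actionable set can never disagree.

Rules ship as editable YAML: the consortium guidelines are data, not code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "GENE_PHENOTYPE_DOMAIN",
    "DrugRule",
    "RecommendationCategory",
    "RuleError",
    "load_rules",
    "dump_rules",
    "default_rules_path",
    "default_rules",
    "is_actionable",
    "recommend",
    "sertraline_recommendation",
    "tca_recommendation",
    "classify_cohort",
]

#: phenotype values a gene can take (RM exists only for CYP2C19);
#: Indeterminate is handled out-of-band and never appears in matrices.
GENE_PHENOTYPE_DOMAIN = {
    "CYP2C19": ("UM", "RM", "NM", "IM", "PM"),
    "CYP2D6": ("UM", "NM", "IM", "PM"),
    "CYP2B6": ("UM", "NM", "IM", "PM"),
    "CYP3A4": ("UM", "NM", "IM", "PM"),
}

INDETERMINATE = "Indeterminate"
STANDARD_CARE = "S"


class RuleError(ValueError):
    """Invalid drug-rule configuration or classification input."""


@dataclass(frozen=True)
class RecommendationCategory:
    label: str
    text: str
    actionable: bool


@dataclass
class DrugRule:
    """One drug's actionability rule (single-gene set or two-gene matrix)."""

    drug: str
    source: str
    genes: tuple[str, ...]
    actionable_set: frozenset = frozenset()  # phenotypes or phenotype pairs
    categories: dict[str, RecommendationCategory] = field(default_factory=dict)
    matrix: dict[tuple[str, str], str] = field(default_factory=dict)
    aliases: tuple[str, ...] = ()
    assumption: bool = False

    def __post_init__(self) -> None:
        if self.source not in ("CPIC", "DPWG"):
            raise RuleError(f"{self.drug}: unknown guideline source {self.source!r}")
        if len(self.genes) not in (1, 2):
            raise RuleError(f"{self.drug}: rules cover one or two genes")
        for gene in self.genes:
            if gene not in GENE_PHENOTYPE_DOMAIN:
                raise RuleError(f"{self.drug}: unknown gene {gene!r}")
        if len(self.genes) == 1:
            if self.matrix:
                raise RuleError(f"{self.drug}: single-gene rules have no matrix")
            domain = set(GENE_PHENOTYPE_DOMAIN[self.genes[0]])
            bad = set(self.actionable_set) - domain
            if bad:
                raise RuleError(f"{self.drug}: phenotypes {sorted(bad)} outside domain")
        else:
            self._validate_matrix()
            # actionability derives from the matrix cells (consistency by
            # construction)
            self.actionable_set = frozenset(
                pair for pair, cat in self.matrix.items() if self.categories[cat].actionable
            )

    def _validate_matrix(self) -> None:
        g1, g2 = self.genes
        expected = {(p1, p2) for p1 in GENE_PHENOTYPE_DOMAIN[g1] for p2 in GENE_PHENOTYPE_DOMAIN[g2]}
        missing = expected - set(self.matrix)
        if missing:
            raise RuleError(
                f"{self.drug}: recommendation matrix missing phenotype pair(s) "
                f"{sorted(missing)[:5]}{'...' if len(missing) > 5 else ''}"
            )
        extra = set(self.matrix) - expected
        if extra:
            raise RuleError(f"{self.drug}: unexpected matrix pairs {sorted(extra)[:5]}")
        for pair, cat in self.matrix.items():
            if cat not in self.categories:
                raise RuleError(f"{self.drug}: cell {pair} names unknown category {cat!r}")
        labels = list(self.categories)
        if len(set(labels)) != len(labels):
            raise RuleError(f"{self.drug}: duplicate category labels")


def load_rules(path: str | Path) -> list[DrugRule]:
    """Load and validate the drug-rule YAML; totality failures name the gap."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = []
    seen: set[str] = set()
    for entry in raw["drugs"]:
        drug = str(entry["drug"])
        if drug in seen:
            raise RuleError(f"duplicate drug {drug!r}")
        seen.add(drug)
        genes = tuple(entry["genes"])
        categories = {
            label: RecommendationCategory(label, str(spec["text"]), bool(spec["actionable"]))
            for label, spec in entry.get("categories", {}).items()
        }
        matrix: dict[tuple[str, str], str] = {}
        for p1, row in entry.get("matrix", {}).items():
            for p2, cat in row.items():
                for p in (p1, p2):
                    if p not in ("UM", "RM", "NM", "IM", "PM"):
                        raise RuleError(f"{drug}: unknown phenotype label {p!r}")
                matrix[(str(p1), str(p2))] = str(cat)
        actionable = frozenset(entry.get("actionable", []))
        for p in actionable:
            if p not in ("UM", "RM", "NM", "IM", "PM"):
                raise RuleError(f"{drug}: unknown phenotype label {p!r} in actionable set")
        rules.append(
            DrugRule(
                drug=drug,
                source=str(entry["source"]),
                genes=genes,
                actionable_set=actionable,
                categories=categories,
                matrix=matrix,
                aliases=tuple(entry.get("aliases", ())),
                assumption=bool(entry.get("assumption", False)),
            )
        )
    return rules


def dump_rules(rules: list[DrugRule], path: str | Path) -> None:
    """Serialize rules back to YAML (round-trip safe)."""
    out = {"drugs": []}
    for r in rules:
        entry: dict = {"drug": r.drug, "source": r.source, "genes": list(r.genes)}
        if r.aliases:
            entry["aliases"] = list(r.aliases)
        if r.assumption:
            entry["assumption"] = True
        if len(r.genes) == 1:
            entry["actionable"] = sorted(r.actionable_set)
        else:
            entry["categories"] = {
                label: {"actionable": c.actionable, "text": c.text}
                for label, c in r.categories.items()
            }
            g1, g2 = r.genes
            entry["matrix"] = {
                p1: {p2: r.matrix[(p1, p2)] for p2 in GENE_PHENOTYPE_DOMAIN[g2]}
                for p1 in GENE_PHENOTYPE_DOMAIN[g1]
            }
        out["drugs"].append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def default_rules_path() -> Path:
    return Path(str(resources.files("pgxaction").joinpath("data/rules.yaml")))


def default_rules() -> list[DrugRule]:
    return load_rules(default_rules_path())


# ---------------------------------------------------------------------------
# classification


def is_actionable(rule: DrugRule, phenotypes: dict[str, str]) -> tuple[bool, bool]:
    """(actionable, indeterminate_flag) for one sample under one rule.

    Indeterminate phenotypes are never actionable; the flag lets cohort
    summaries count them separately from true negatives.
    """
    values = []
    for gene in rule.genes:
        if gene not in phenotypes:
            raise RuleError(f"{rule.drug}: missing {gene} phenotype")
        values.append(phenotypes[gene])
    if INDETERMINATE in values:
        return False, True
    if len(rule.genes) == 1:
        return values[0] in rule.actionable_set, False
    return tuple(values) in rule.actionable_set, False


def recommend(rule: DrugRule, phenotypes: dict[str, str]) -> RecommendationCategory | None:
    """Matrix lookup for a two-gene drug; None for Indeterminate input."""
    if len(rule.genes) != 2:
        raise RuleError(f"{rule.drug}: no recommendation matrix (single-gene rule)")
    values = tuple(phenotypes[g] for g in rule.genes)
    if INDETERMINATE in values:
        return None
    try:
        label = rule.matrix[values]
    except KeyError as exc:
        raise RuleError(f"{rule.drug}: phenotype pair {values} outside matrix") from exc
    return rule.categories[label]


def _rule_by_drug(rules: list[DrugRule], drug: str) -> DrugRule:
    for r in rules:
        if r.drug == drug or drug in r.aliases:
            return r
    raise RuleError(f"no rule for drug {drug!r}")


def sertraline_recommendation(
    c19: str, b6: str, rule: DrugRule | None = None
) -> RecommendationCategory | None:
    rule = rule or _rule_by_drug(default_rules(), "sertraline")
    return recommend(rule, {"CYP2C19": c19, "CYP2B6": b6})


def tca_recommendation(
    c19: str, d6: str, rule: DrugRule | None = None
) -> RecommendationCategory | None:
    rule = rule or _rule_by_drug(default_rules(), "amitriptyline")
    return recommend(rule, {"CYP2C19": c19, "CYP2D6": d6})


def classify_cohort(phenotypes, rules: list[DrugRule]):
    """Classify every sample against every rule.

    ``phenotypes`` is the tidy per-sample per-gene phenotype DataFrame from
    the phenotyper (columns sample_id, gene, phenotype). Returns a tidy
    DataFrame (sample_id, drug, actionable, category, flag) where
    ``category`` is the matrix cell for two-gene drugs and empty otherwise.
    """
    import pandas as pd

    by_sample: dict[str, dict[str, str]] = {}
    for row in phenotypes.itertuples(index=False):
        by_sample.setdefault(row.sample_id, {})[row.gene] = row.phenotype

    needed = {g for r in rules for g in r.genes}
    for sample_id, genes in by_sample.items():
        missing = needed - set(genes)
        if missing:
            offenders = [r.drug for r in rules if set(r.genes) & missing]
            raise RuleError(
                f"sample {sample_id}: missing phenotypes for {sorted(missing)} "
                f"required by {offenders}"
            )

    rows = []
    for sample_id in sorted(by_sample):
        sample_ph = by_sample[sample_id]
        for rule in rules:
            actionable, flagged = is_actionable(rule, sample_ph)
            category = ""
            if len(rule.genes) == 2:
                rec = recommend(rule, sample_ph)
                category = rec.label if rec is not None else ""
            rows.append(
                {
                    "sample_id": sample_id,
                    "drug": rule.drug,
                    "actionable": actionable,
                    "category": category,
                    "flag": "indeterminate" if flagged else "",
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "drug", "actionable", "category", "flag"])
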