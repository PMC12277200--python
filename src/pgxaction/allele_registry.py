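"""Star-allele definition tables for the four psychotropic-relevant CYP genes.

A *star allele* is a named haplotype of a pharmacogene (e.g. ``CYP2D6*4``)
defined by a fixed set of small variants and carrying a curated function
class (normal / decreased / no_function / increased / uncertain) and, for
CYP2D6, an activity value used in activity-score arithmetic.

The on-disk format is a plain TSV with columns
``gene  allele  variants  function  activity  build`` where ``variants`` is a
semicolon-joined list of ``chrom:pos:ref:alt`` strings (``-`` for none,
1-based positions matching VCF POS). Sub-alleles are collapsed to core
alleles; the shipped fixture table uses core alleles only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "GENES",
    "FUNCTION_CLASSES",
    "VariantKey",
    "AlleleDefinition",
    "AlleleTable",
    "AlleleTableError",
    "load_allele_table",
    "write_allele_table",
    "alleles_compatible_with",
    "default_allele_table_path",
    "default_allele_table",
]

GENES = ("CYP2C19", "CYP2D6", "CYP2B6", "CYP3A4")
FUNCTION_CLASSES = ("normal", "decreased", "no_function", "increased", "uncertain")

#: CYP2D6 whole-gene deletion allele; carries no variants and is introduced
#: only through copy-number evidence, never through genotype matching.
DELETION_ALLELE = "*5"

_NUCS = frozenset("ACGT")


class AlleleTableError(ValueError):
    """Malformed or inconsistent allele-definition input."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """A small variant in 1-based VCF coordinates."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise AlleleTableError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise AlleleTableError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise AlleleTableError(f"ref == alt at {self.chrom}:{self.pos}")
        for seq in (self.ref, self.alt):
            if not set(seq) <= _NUCS:
                raise AlleleTableError(f"non-ACGT sequence {seq!r} at {self.chrom}:{self.pos}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        parts = text.strip().split(":")
        if len(parts) != 4:
            raise AlleleTableError(f"cannot parse variant {text!r} (want chrom:pos:ref:alt)")
        chrom, pos, ref, alt = parts
        try:
            position = int(pos)
        except ValueError as exc:
            raise AlleleTableError(f"non-integer position in {text!r}") from exc
        return cls(chrom, position, ref.upper(), alt.upper())


@dataclass(frozen=True)
class AlleleDefinition:
    """One named star allele with its defining variants and curated function."""

    gene: str
    name: str
    defining_variants: frozenset[VariantKey]
    function_class: str
    activity_value: float | str  # non-negative number, or "uncertain"

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise AlleleTableError(f"unknown gene {self.gene!r}")
        if self.function_class not in FUNCTION_CLASSES:
            raise AlleleTableError(
                f"{self.gene}{self.name}: unknown function class {self.function_class!r}"
            )
        if isinstance(self.activity_value, str) and self.activity_value != "uncertain":
            raise AlleleTableError(
                f"{self.gene}{self.name}: activity must be a number or 'uncertain'"
            )
        if isinstance(self.activity_value, (int, float)) and self.activity_value < 0:
            raise AlleleTableError(f"{self.gene}{self.name}: negative activity value")

    @property
    def is_reference(self) -> bool:
        return self.name == "*1"

    @property
    def is_deletion(self) -> bool:
        return self.gene == "CYP2D6" and self.name == DELETION_ALLELE


@dataclass
class AlleleTable:
    """Validated per-gene allele definitions plus an inverted variant index."""

    definitions: dict[str, list[AlleleDefinition]]
    build: str = "synthetic"
    variant_index: dict[VariantKey, list[AlleleDefinition]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()
        self._reindex()

    def _validate(self) -> None:
        for gene, defs in self.definitions.items():
            if gene not in GENES:
                raise AlleleTableError(f"unknown gene {gene!r}")
            seen: set[str] = set()
            for d in defs:
                if d.gene != gene:
                    raise AlleleTableError(f"allele {d.name} filed under wrong gene {gene}")
                if d.name in seen:
                    raise AlleleTableError(f"duplicate allele name {gene}{d.name}")
                seen.add(d.name)
            if "*1" not in seen:
                raise AlleleTableError(f"{gene}: missing reference allele *1")
            ref = self.get(gene, "*1")
            if ref.defining_variants or ref.function_class != "normal":
                raise AlleleTableError(f"{gene}*1 must have no variants and normal function")
            if gene == "CYP2D6":
                for d in defs:
                    if d.function_class != "uncertain" and isinstance(d.activity_value, str):
                        raise AlleleTableError(
                            f"CYP2D6{d.name}: activity value required for "
                            f"{d.function_class} function"
                        )

    def _reindex(self) -> None:
        index: dict[VariantKey, list[AlleleDefinition]] = {}
        for defs in self.definitions.values():
            for d in defs:
                for v in d.defining_variants:
                    index.setdefault(v, []).append(d)
        self.variant_index = index

    # -- accessors -------------------------------------------------------

    def genes(self) -> tuple[str, ...]:
        return tuple(g for g in GENES if g in self.definitions)

    def alleles(self, gene: str) -> list[AlleleDefinition]:
        try:
            return self.definitions[gene]
        except KeyError as exc:
            raise AlleleTableError(f"gene {gene!r} not in table") from exc

    def get(self, gene: str, name: str) -> AlleleDefinition:
        for d in self.alleles(gene):
            if d.name == name:
                return d
        raise AlleleTableError(f"allele {gene}{name} not in table")

    def gene_of_variant(self, key: VariantKey) -> str | None:
        hits = self.variant_index.get(key)
        return hits[0].gene if hits else None

    @property
    def total_alleles(self) -> int:
        return sum(len(defs) for defs in self.definitions.values())


_COLUMNS = ["gene", "allele", "variants", "function", "activity", "build"]


def _parse_activity(text: str) -> float | str:
    text = text.strip()
    if text in ("", "-", "uncertain"):
        return "uncertain" if text == "uncertain" else "uncertain"
    return float(text)


def load_allele_table(path: str | Path, gene_filter: Iterable[str] | None = None) -> AlleleTable:
    """Read a PharmVar-style definition TSV into a validated :class:`AlleleTable`.

    Rows whose gene is outside ``gene_filter`` (when given) are skipped.
    Structural problems (missing columns, duplicate allele names, unknown
    function classes, unparseable variants) raise :class:`AlleleTableError`.
    """
    path = Path(path)
    wanted = set(gene_filter) if gene_filter is not None else None
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _COLUMNS[:5] if c not in header]
        if missing:
            raise AlleleTableError(f"{path}: missing columns {missing}")
        col = {name: header.index(name) for name in header}
        defs: dict[str, list[AlleleDefinition]] = {}
        build = "unspecified"
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                raise AlleleTableError(f"{path}:{lineno}: short row")
            gene = fields[col["gene"]]
            if wanted is not None and gene not in wanted:
                continue
            variants_text = fields[col["variants"]].strip()
            if variants_text in ("", "-"):
                variants: frozenset[VariantKey] = frozenset()
            else:
                variants = frozenset(
                    VariantKey.parse(v) for v in variants_text.split(";") if v.strip()
                )
            activity_text = fields[col["activity"]].strip()
            activity: float | str
            if activity_text in ("", "-", "uncertain"):
                activity = "uncertain"
            else:
                try:
                    activity = float(activity_text)
                except ValueError as exc:
                    raise AlleleTableError(f"{path}:{lineno}: bad activity {activity_text!r}") from exc
            definition = AlleleDefinition(
                gene=gene,
                name=fields[col["allele"]],
                defining_variants=variants,
                function_class=fields[col["function"]],
                activity_value=activity,
            )
            if "build" in col:
                build = fields[col["build"]] or build
            defs.setdefault(gene, []).append(definition)
    return AlleleTable(definitions=defs, build=build)


def write_allele_table(table: AlleleTable, path: str | Path) -> None:
    """Serialize a table back to the definition TSV (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for gene in table.genes():
            for d in table.alleles(gene):
                variants = ";".join(str(v) for v in sorted(d.defining_variants)) or "-"
                activity = (
                    d.activity_value
                    if isinstance(d.activity_value, str)
                    else format(d.activity_value, "g")
                )
                fh.write(
                    "\t".join([gene, d.name, variants, d.function_class, str(activity), table.build])
                    + "\n"
                )


def alleles_compatible_with(
    table: AlleleTable, gene: str, observed: Iterable[VariantKey]
) -> list[AlleleDefinition]:
    """Alleles whose defining variants are all contained in ``observed``.

    Always includes the reference ``*1`` (empty defining set). The CYP2D6
    whole-gene deletion is excluded: it is evidenced by copy number, not by
    small variants.
    """
    observed_set = set(observed)
    out = [
        d
        for d in table.alleles(gene)
        if not d.is_deletion and d.defining_variants <= observed_set
    ]
    return out


def default_allele_table_path() -> Path:
    """Path of the packaged 490-allele fixture table (synthetic coordinates)."""
    return Path(str(resources.files("pgxaction").joinpath("data/alleles.tsv")))


def default_allele_table() -> AlleleTable:
    return load_allele_table(default_allele_table_path())
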