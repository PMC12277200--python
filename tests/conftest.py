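import pytest
from hypothesis import HealthCheck, settings

from pgxaction.allele_registry import AlleleDefinition, AlleleTable, VariantKey
from pgxaction.allele_registry import default_allele_table
from pgxaction.guideline_engine import default_rules
from pgxaction.phenotyper import default_phenotype_config

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def make_allele(gene, name, variants, function, activity):
    """Shorthand builder: variants as list of (pos, ref, alt) on a per-gene contig."""
    keys = frozenset(VariantKey(f"chr_{gene}", pos, ref, alt) for pos, ref, alt in variants)
    return AlleleDefinition(gene, name, keys, function, activity)


@pytest.fixture(scope="session")
def full_table():
    return default_allele_table()


@pytest.fixture(scope="session")
def phenoconf():
    return default_phenotype_config()


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture
def mini_d6_table():
    """Three-variant CYP2D6 table with pairwise-disjoint definitions plus *5."""
    return AlleleTable(
        definitions={
            "CYP2D6": [
                make_allele("CYP2D6", "*1", [], "normal", 1.0),
                make_allele("CYP2D6", "*4", [(100, "G", "A")], "no_function", 0.0),
                make_allele("CYP2D6", "*5", [], "no_function", 0.0),
                make_allele("CYP2D6", "*10", [(200, "C", "T")], "decreased", 0.25),
            ]
        }
    )


@pytest.fixture
def overlap_d6_table():
    """CYP2D6 table where *36 carries the union of *4's and *10's variants."""
    return AlleleTable(
        definitions={
            "CYP2D6": [
                make_allele("CYP2D6", "*1", [], "normal", 1.0),
                make_allele("CYP2D6", "*4", [(100, "G", "A")], "no_function", 0.0),
                make_allele("CYP2D6", "*10", [(200, "C", "T")], "decreased", 0.25),
                make_allele(
                    "CYP2D6", "*36", [(100, "G", "A"), (200, "C", "T")], "no_function", 0.0
                ),
            ]
        }
    )
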