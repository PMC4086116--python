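import pytest

from mirprio.fixtures import FixtureSpec, make_bundle
from mirprio.io import AnnotationCorpus, Concept, GeneList


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down synthetic world for fast unit tests."""
    return FixtureSpec(
        n_genes=60,
        categories=("GO_BP", "Pathway"),
        n_concepts_per_category=10,
        concept_size_range=(4, 8),
        n_mirs=8,
        targets_per_mir=8,
        signal_module_size=12,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return make_bundle(small_spec)


@pytest.fixture(scope="session")
def default_spec():
    return FixtureSpec()


@pytest.fixture
def toy_corpus():
    """Hand-built two-category corpus over genes A..J."""
    genes = [chr(ord("A") + i) for i in range(10)]

    def concept(cid, members):
        return Concept(cid, f"name {cid}", frozenset(members))

    categories = {
        "GO_BP": {
            "BP1": concept("BP1", ["A", "B", "C"]),
            "BP2": concept("BP2", ["C", "D", "E", "F"]),
            "BP3": concept("BP3", genes),
        },
        "Pathway": {
            "P1": concept("P1", ["A", "B"]),
            "P2": concept("P2", ["G", "H", "I", "J"]),
            "P3": concept("P3", genes),
        },
    }
    return AnnotationCorpus(categories=categories, background=frozenset(genes))


@pytest.fixture
def toy_query():
    return GeneList(genes=("A", "B", "C"), label="test")
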