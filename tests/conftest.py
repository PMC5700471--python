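import pytest

from phenorec.corpus import DocumentRecord, Ontology
from phenorec.fixtures import FixtureSpec, generate_fixture
from phenorec.lexicon import WordLists
from phenorec.preprocess import preprocess_document


@pytest.fixture(scope="session")
def toy_bundle():
    """Default synthetic bundle: every phenomenon present."""
    return generate_fixture(FixtureSpec(n_terms=8, n_docs=8, seed=11))


@pytest.fixture(scope="session")
def clean_bundle():
    """Consistently annotated bundle (no deliberate under-annotation)."""
    return generate_fixture(
        FixtureSpec(n_terms=8, n_docs=10, seed=3, unannotated_rate=0.0, nesting_rate=1.0)
    )


@pytest.fixture(scope="session")
def word_lists():
    return WordLists.default()


@pytest.fixture(scope="session")
def tiny_ontology():
    return Ontology(
        terms={
            "HP_0000077": "Abnormality of the kidney",
            "HP_0000110": "Renal dysplasia",
            "HP_0100526": "tumours",
            "HP_0004375": "tumours of the nervous system",
            "HP_0000811": "genital anomalies",
        },
        synonyms={"HP_0000110": {"renal dysplasia", "kidney dysplasia"}},
        parents={"HP_0004375": {"HP_0100526"}},
    )


def make_doc(text: str, doc_id: str = "d1"):
    """Preprocess a raw string into (DocumentRecord, sentences)."""
    doc = DocumentRecord(doc_id, text)
    return doc, preprocess_document(doc)
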