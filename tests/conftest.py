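import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cuitrans import AnnotatedCorpus, Annotation, Document

# Worked example: an annotated English sentence and its Dutch translation
# with embedded markers, used across the suite.
EN_TEXT = "Temporary kidney enlargement in the newborn infant"
EN_EMBEDDED = (
    "Temporary [[kidney enlargement][C0542518]] in the "
    "[[newborn infant][C0021289]]"
)
NL_EMBEDDED = (
    "Tijdelijke [[niervergroting][C0542518]] bij de "
    "[[pasgeboren baby][C0021289]]"
)
NL_CLEAN = "Tijdelijke niervergroting bij de pasgeboren baby"


@pytest.fixture
def en_document():
    return Document("d1", EN_TEXT)


@pytest.fixture
def en_annotations():
    return [
        Annotation("d1", "C0542518", 10, 28, "kidney enlargement"),
        Annotation("d1", "C0021289", 36, 50, "newborn infant"),
    ]


@pytest.fixture
def en_corpus(en_document, en_annotations):
    return AnnotatedCorpus("mantra-ema", "en", [en_document], en_annotations)
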