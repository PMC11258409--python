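"""Corpus data model, tabular/PubTator/brat readers, and splitting."""

import pytest
from hypothesis import given, strategies as st

from cuitrans import (
    AnnotatedCorpus,
    Annotation,
    CorpusFormatError,
    CorpusValidationError,
    Document,
    read_brat,
    read_corpus_tables,
    read_pubtator,
    split_corpus,
    write_corpus_tables,
)
from cuitrans.synthetic import GeneratorConfig, generate_corpus

from conftest import EN_TEXT


class TestDataModel:
    def test_slice_invariant_enforced(self):
        doc = Document("d1", EN_TEXT)
        bad = Annotation("d1", "C0542518", 10, 29, "kidney enlargement")
        with pytest.raises(CorpusValidationError, match="span_text mismatch"):
            AnnotatedCorpus("c", "en", [doc], [bad])

    @pytest.mark.parametrize(
        "annotation, message",
        [
            (Annotation("ghost", "C0542518", 0, 4, "Temp"), "unknown document"),
            (Annotation("d1", "C0542518", 40, 60, "x" * 20), "out of range"),
            (Annotation("d1", "0542518", 10, 28, "kidney enlargement"), "malformed CUI"),
            (Annotation("d1", "Cx", 10, 28, "kidney enlargement"), "malformed CUI"),
        ],
    )
    def test_invalid_annotations_rejected(self, annotation, message):
        doc = Document("d1", EN_TEXT)
        with pytest.raises(CorpusValidationError, match=message):
            AnnotatedCorpus("c", "en", [doc], [annotation])

    def test_duplicate_and_empty_document_ids_rejected(self):
        with pytest.raises(CorpusValidationError, match="duplicate"):
            AnnotatedCorpus("c", "en", [Document("d", "a"), Document("d", "b")])
        with pytest.raises(CorpusValidationError, match="empty"):
            AnnotatedCorpus("c", "en", [Document("", "a")])

    def test_annotations_sorted_by_span_within_document(self):
        doc = Document("d1", "abcdef")
        anns = [
            Annotation("d1", "C2", 3, 5, "de"),
            Annotation("d1", "C1", 0, 2, "ab"),
        ]
        corpus = AnnotatedCorpus("c", "en", [doc], anns)
        assert [a.cui for a in corpus.annotations] == ["C1", "C2"]


class TestTables:
    def test_empty_tables_give_empty_corpus(self):
        corpus = read_corpus_tables("DocumentId\tText\n",
                                    "DocumentId\tCUI\tSpanStart\tSpanEnd\tSpanText\n")
        assert corpus.n_documents == 0 and corpus.n_annotations == 0

    def test_worked_example_reads_and_writes(self, en_corpus):
        docs_t, anns_t = write_corpus_tables(en_corpus)
        assert "C0542518\t10\t28\tkidney enlargement" in anns_t
        back = read_corpus_tables(docs_t, anns_t, name=en_corpus.name)
        assert back.documents == en_corpus.documents
        assert back.annotations == en_corpus.annotations

    def test_missing_column_is_format_error(self):
        with pytest.raises(CorpusFormatError, match="header"):
            read_corpus_tables("DocumentId\n", "DocumentId\tCUI\tSpanStart\tSpanEnd\tSpanText\n")

    def test_mismatching_span_text_is_validation_error(self):
        docs = "DocumentId\tText\nd1\tTemporary kidney enlargement in the newborn infant\n"
        anns = ("DocumentId\tCUI\tSpanStart\tSpanEnd\tSpanText\n"
                "d1\tC0542518\t10\t29\tkidney enlargement\n")
        with pytest.raises(CorpusValidationError, match="d1"):
            read_corpus_tables(docs, anns)

    def test_empty_corpus_round_trips_as_header_only_tables(self):
        corpus = AnnotatedCorpus("c", "en", [], [])
        docs_t, anns_t = write_corpus_tables(corpus)
        assert docs_t == "DocumentId\tText\n"
        assert anns_t == "DocumentId\tCUI\tSpanStart\tSpanEnd\tSpanText\n"

    def test_texts_with_tabs_newlines_backslashes_round_trip(self):
        text = "line1\nline2\twith\\escapes\nC0000000 [[x][C1]]"
        corpus = AnnotatedCorpus(
            "c", "en",
            [Document("d1", text)],
            [Annotation("d1", "C7", 0, 5, "line1"),
             Annotation("d1", "C8", 6, 11, "line2")],
        )
        back = read_corpus_tables(*write_corpus_tables(corpus))
        assert back.documents == corpus.documents
        assert back.annotations == corpus.annotations

    @pytest.mark.parametrize("seed", range(20))
    def test_random_synthetic_corpora_round_trip(self, seed):
        corpus = generate_corpus(
            GeneratorConfig(n_documents=5, mean_sentences_per_document=3,
                            annotation_density=4, seed=seed)
        )
        back = read_corpus_tables(*write_corpus_tables(corpus),
                                  name=corpus.name, language=corpus.language)
        assert back.documents == corpus.documents
        assert back.annotations == corpus.annotations


PUBTATOR_DOC = (
    "123|t|Temporary kidney enlargement in the newborn infant\n"
    "123|a|The abstract body mentions nothing.\n"
    "123\t10\t28\tkidney enlargement\tT033\tUMLS:C0542518\n"
    "123\t36\t50\tnewborn infant\tT100\tC0021289\n"
)


class TestPubtator:
    def test_document_without_annotations(self):
        corpus = read_pubtator("9|t|A title.\n9|a|An abstract.\n")
        assert corpus.n_documents == 1 and corpus.n_annotations == 0
        assert corpus.documents[0].text == "A title.\nAn abstract."

    def test_umls_prefix_stripped_and_offsets_validated(self):
        corpus = read_pubtator(PUBTATOR_DOC)
        anns = corpus.annotations
        assert {a.cui for a in anns} == {"C0542518", "C0021289"}
        assert anns[0].span_start == 10 and anns[0].span_end == 28

    def test_title_only_document(self):
        text = ("123|t|Temporary kidney enlargement in the newborn infant\n"
                "123\t10\t28\tkidney enlargement\tT033\tUMLS:C0542518\n")
        corpus = read_pubtator(text)
        assert corpus.annotations[0].span_text == "kidney enlargement"

    def test_mention_mismatch_is_validation_error(self):
        bad = PUBTATOR_DOC.replace("kidney enlargement\tT033",
                                   "kidney enlargemenX\tT033")
        with pytest.raises(CorpusValidationError):
            read_pubtator(bad)

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(CorpusFormatError, match="line 2"):
            read_pubtator("9|t|A title.\ngarbage line\n")


class TestBrat:
    def test_empty_ann_gives_no_annotations(self):
        corpus = read_brat("Some text.", "")
        assert corpus.n_documents == 1 and corpus.n_annotations == 0

    def test_type_field_carries_cui(self):
        corpus = read_brat(EN_TEXT, "T1\tC0542518 10 28\tkidney enlargement\n")
        a = corpus.annotations[0]
        assert (a.cui, a.span_start, a.span_end) == ("C0542518", 10, 28)

    def test_cui_from_notes_dialect(self):
        ann = ("T1\tDisorder 10 28\tkidney enlargement\n"
               "#1\tAnnotatorNotes T1\tCUI-less? no: C0542518\n")
        corpus = read_brat(EN_TEXT, ann, cui_from_notes=True)
        assert corpus.annotations[0].cui == "C0542518"

    def test_discontinuous_span_rejected(self):
        with pytest.raises(CorpusFormatError, match="discontinuous"):
            read_brat(EN_TEXT, "T1\tC0542518 10 28;30 35\tkidney enlargement\n")


class TestSplit:
    def test_80_20_on_ten_documents(self):
        corpus = AnnotatedCorpus(
            "c", "en", [Document(f"d{i}", "text") for i in range(10)], []
        )
        result = split_corpus(corpus, 0.8, seed=7)
        assert result.train.n_documents == 8
        assert result.test.n_documents == 2

    def test_deterministic_for_fixed_seed(self):
        corpus = generate_corpus(GeneratorConfig(n_documents=30, seed=5))
        a = split_corpus(corpus, 0.8, seed=11)
        b = split_corpus(corpus, 0.8, seed=11)
        assert a.train.document_ids == b.train.document_ids
        assert a.test.document_ids == b.test.document_ids

    @pytest.mark.parametrize("fraction", [0.5, 0.8, 0.9])
    @pytest.mark.parametrize("seed", range(5))
    def test_partition_properties(self, fraction, seed):
        corpus = generate_corpus(
            GeneratorConfig(n_documents=37, mean_sentences_per_document=2,
                            annotation_density=2, seed=seed)
        )
        result = split_corpus(corpus, fraction, seed=seed)
        train_ids = set(result.train.document_ids)
        test_ids = set(result.test.document_ids)
        assert train_ids | test_ids == set(corpus.document_ids)
        assert train_ids & test_ids == set()
        assert len(train_ids) == int(fraction * 37 + 0.5)
        # annotations travel with their documents, none dropped
        assert (result.train.n_annotations + result.test.n_annotations
                == corpus.n_annotations)

    def test_large_corpus_exhaustive_membership(self):
        corpus = AnnotatedCorpus(
            "c", "en", [Document(f"d{i}", "t") for i in range(1000)], []
        )
        result = split_corpus(corpus, 0.8, seed=0)
        assert result.train.n_documents == 800
        assert result.test.n_documents == 200
        counts = {}
        for i in list(result.train.document_ids) + list(result.test.document_ids):
            counts[i] = counts.get(i, 0) + 1
        assert all(v == 1 for v in counts.values()) and len(counts) == 1000

    def test_empty_corpus_rejected(self):
        with pytest.raises(CorpusValidationError):
            split_corpus(AnnotatedCorpus("c", "en", [], []), 0.8, 0)
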