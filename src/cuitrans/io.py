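"""Reading and writing annotated corpora.

Three on-disk representations are supported:

* the standardized tabular format — a documents table (``DocumentId``,
  ``Text``) and an annotations table (``DocumentId``, ``CUI``, ``SpanStart``,
  ``SpanEnd``, ``SpanText``), both tab-separated UTF-8 with a header row.
  Literal tabs, newlines and backslashes inside text fields are escaped as
  ``\\t``, ``\\n`` and ``\\\\`` on write and unescaped on read, so one table
  row is always one physical line;
* the PubTator exchange format (``PMID|t|title`` / ``PMID|a|abstract`` blocks
  followed by tab-separated mention lines), used by MedMentions releases;
* brat standoff (``.txt`` text plus ``.ann`` entity lines).

All readers validate the full corpus invariant set on return, so a span/text
mismatch anywhere in the input is reported with the offending record.
"""

from __future__ import annotations

import io as _io
import re
from typing import IO, Iterable, Iterator, Union

from .corpus import AnnotatedCorpus, Annotation, Document
from .errors import CorpusFormatError, CorpusValidationError

Stream = Union[str, IO[str]]

DOCUMENTS_HEADER = ("DocumentId", "Text")
ANNOTATIONS_HEADER = ("DocumentId", "CUI", "SpanStart", "SpanEnd", "SpanText")


def _as_lines(stream: Stream) -> list[str]:
    if isinstance(stream, str):
        data = stream
    else:
        data = stream.read()
    return data.split("\n")


def escape_field(value: str) -> str:
    return value.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def unescape_field(value: str) -> str:
    out: list[str] = []
    it = iter(range(len(value)))
    i = 0
    while i < len(value):
        c = value[i]
        if c == "\\" and i + 1 < len(value):
            nxt = value[i + 1]
            if nxt == "t":
                out.append("\t")
                i += 2
                continue
            if nxt == "n":
                out.append("\n")
                i += 2
                continue
            if nxt == "\\":
                out.append("\\")
                i += 2
                continue
        out.append(c)
        i += 1
    return "".join(out)


def _parse_table(
    stream: Stream, expected_header: tuple[str, ...], what: str
) -> list[list[str]]:
    lines = _as_lines(stream)
    if lines and lines[-1] == "":
        lines = lines[:-1]
    if not lines:
        raise CorpusFormatError(f"{what} table is empty (missing header row)")
    header = tuple(lines[0].split("\t"))
    if header != expected_header:
        raise CorpusFormatError(
            f"{what} table header {header!r} != expected {expected_header!r}"
        )
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(expected_header):
            raise CorpusFormatError(
                f"{what} table line {lineno}: expected "
                f"{len(expected_header)} fields, got {len(fields)}"
            )
        rows.append(fields)
    return rows


def read_corpus_tables(
    documents_table: Stream,
    annotations_table: Stream,
    name: str = "corpus",
    language: str = "en",
) -> AnnotatedCorpus:
    """Read the standardized tabular format into a validated corpus."""
    doc_rows = _parse_table(documents_table, DOCUMENTS_HEADER, "documents")
    ann_rows = _parse_table(annotations_table, ANNOTATIONS_HEADER, "annotations")
    documents = [Document(r[0], unescape_field(r[1])) for r in doc_rows]
    annotations = []
    for r in ann_rows:
        try:
            start, end = int(r[2]), int(r[3])
        except ValueError as exc:
            raise CorpusFormatError(
                f"non-integer offsets in annotation row {r!r}"
            ) from exc
        annotations.append(Annotation(r[0], r[1], start, end, unescape_field(r[4])))
    return AnnotatedCorpus(name, language, documents, annotations)


def write_corpus_tables(corpus: AnnotatedCorpus) -> tuple[str, str]:
    """Serialize a corpus to (documents_table, annotations_table) strings.

    Round-trips: ``read_corpus_tables(*write_corpus_tables(c))`` reproduces
    ``c`` record for record.
    """
    doc_lines = ["\t".join(DOCUMENTS_HEADER)]
    for d in corpus.documents:
        doc_lines.append(f"{d.document_id}\t{escape_field(d.text)}")
    ann_lines = ["\t".join(ANNOTATIONS_HEADER)]
    for a in corpus.annotations:
        ann_lines.append(
            "\t".join(
                [
                    a.document_id,
                    a.cui,
                    str(a.span_start),
                    str(a.span_end),
                    escape_field(a.span_text),
                ]
            )
        )
    return "\n".join(doc_lines) + "\n", "\n".join(ann_lines) + "\n"


# -- PubTator ------------------------------------------------------------

_PUBTATOR_TEXT_RE = re.compile(r"^(?P<pmid>[^|]+)\|(?P<kind>[ta])\|(?P<text>.*)$")


def read_pubtator(stream: Stream, name: str = "pubtator", language: str = "en") -> AnnotatedCorpus:
    """Read a PubTator-dialect stream.

    Each document block is ``PMID|t|title`` optionally followed by
    ``PMID|a|abstract`` and then tab-separated mention lines
    ``PMID<TAB>start<TAB>end<TAB>mention<TAB>type<TAB>concept-id``.  Document
    text is the title plus, when an abstract is present, a newline and the
    abstract.  Concept ids are normalized to bare CUIs (a leading ``UMLS:``
    prefix is stripped).
    """
    titles: dict[str, str] = {}
    abstracts: dict[str, str] = {}
    order: list[str] = []
    ann_rows: list[tuple[str, str, int, int, str, int]] = []
    for lineno, line in enumerate(_as_lines(stream), start=1):
        if not line.strip():
            continue
        m = _PUBTATOR_TEXT_RE.match(line)
        if m and "\t" not in line.split("|", 2)[0]:
            pmid, kind, text = m.group("pmid"), m.group("kind"), m.group("text")
            if kind == "t":
                if pmid in titles:
                    raise CorpusFormatError(
                        f"line {lineno}: duplicate title for {pmid!r}"
                    )
                titles[pmid] = text
                order.append(pmid)
            else:
                abstracts[pmid] = text
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise CorpusFormatError(
                f"line {lineno}: malformed PubTator line {line!r}"
            )
        pmid, start_s, end_s, mention, _type, concept = fields[:6]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise CorpusFormatError(
                f"line {lineno}: non-integer offsets in {line!r}"
            ) from exc
        cui = concept.split("UMLS:", 1)[1] if concept.startswith("UMLS:") else concept
        ann_rows.append((pmid, cui, start, end, mention, lineno))

    documents = []
    for pmid in order:
        text = titles[pmid]
        if pmid in abstracts:
            text = text + "\n" + abstracts[pmid]
        documents.append(Document(pmid, text))
    annotations = [
        Annotation(pmid, cui, start, end, mention)
        for pmid, cui, start, end, mention, _ in ann_rows
    ]
    return AnnotatedCorpus(name, language, documents, annotations)


# -- brat standoff -------------------------------------------------------

_BRAT_ENTITY_RE = re.compile(
    r"^(?P<id>T\d+)\t(?P<type>\S+) (?P<offsets>[0-9; ]+)\t(?P<text>.*)$"
)
_BRAT_NOTE_RE = re.compile(
    r"^#\d+\tAnnotatorNotes (?P<ref>T\d+)\t(?P<note>.*)$"
)
_CUI_TOKEN_RE = re.compile(r"C[0-9]+")


def read_brat(
    text_stream: Stream,
    ann_stream: Stream,
    document_id: str = "doc1",
    name: str = "brat",
    language: str = "en",
    cui_from_notes: bool = False,
) -> AnnotatedCorpus:
    """Read one brat standoff document (.txt + .ann).

    By default the entity TYPE field carries the CUI
    (``T1<TAB>C0542518 10 28<TAB>kidney enlargement``); with
    ``cui_from_notes`` the CUI is taken from an ``AnnotatorNotes`` line
    referencing the entity.  Discontinuous spans (``;``-separated fragments)
    are rejected: they cannot be represented as a single standoff interval.
    """
    text = text_stream if isinstance(text_stream, str) else text_stream.read()
    entities: list[tuple[str, str, int, int, str]] = []
    notes: dict[str, str] = {}
    for lineno, line in enumerate(_as_lines(ann_stream), start=1):
        if not line.strip():
            continue
        note = _BRAT_NOTE_RE.match(line)
        if note:
            m = _CUI_TOKEN_RE.search(note.group("note"))
            if m:
                notes[note.group("ref")] = m.group(0)
            continue
        if line.startswith("#"):
            continue
        ent = _BRAT_ENTITY_RE.match(line)
        if not ent:
            raise CorpusFormatError(
                f".ann line {lineno}: malformed entity line {line!r}"
            )
        offsets = ent.group("offsets").strip()
        if ";" in offsets:
            raise CorpusFormatError(
                f".ann line {lineno}: discontinuous span {offsets!r} is not "
                "supported"
            )
        try:
            start_s, end_s = offsets.split()
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise CorpusFormatError(
                f".ann line {lineno}: bad offsets {offsets!r}"
            ) from exc
        entities.append((ent.group("id"), ent.group("type"), start, end, ent.group("text")))

    annotations = []
    for tid, type_, start, end, span_text in entities:
        if cui_from_notes:
            if tid not in notes:
                raise CorpusFormatError(
                    f"entity {tid}: no AnnotatorNotes line supplies a CUI"
                )
            cui = notes[tid]
        else:
            cui = type_
        annotations.append(Annotation(document_id, cui, start, end, span_text))
    return AnnotatedCorpus(
        name, language, [Document(document_id, text)], annotations
    )
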