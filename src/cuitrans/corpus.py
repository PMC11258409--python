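"""Corpus data model: documents with standoff concept annotations.

A corpus pairs free text documents with standoff annotations, each linking a
character span to a UMLS Concept Unique Identifier (CUI).  Offsets are
0-based, end-exclusive, and counted in Unicode code points.  Annotations are
never allowed to drift from the text: every annotation's ``span_text`` must
equal the referenced document's text sliced at ``[span_start, span_end)``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import CorpusValidationError

#: A CUI is the literal letter "C" followed by decimal digits (canonically 7).
CUI_PATTERN = re.compile(r"C[0-9]+\Z")


@dataclass(frozen=True)
class Document:
    """One text document.

    ``text`` is an arbitrary unicode string; it may contain newlines, tabs
    and bracket characters and is never normalized (any mutation would
    invalidate the standoff offsets of its annotations).
    """

    document_id: str
    text: str


@dataclass(frozen=True)
class Annotation:
    """One standoff concept annotation.

    Offsets are 0-based code-point indices into the referenced document's
    text; ``span_start`` is inclusive and ``span_end`` exclusive.
    """

    document_id: str
    cui: str
    span_start: int
    span_end: int
    span_text: str

    def sort_key(self) -> tuple[int, int, str]:
        return (self.span_start, self.span_end, self.cui)


@dataclass(frozen=True)
class AnnotatedCorpus:
    """Documents plus their standoff CUI annotations.

    Annotations are stored grouped by document (in document order) and sorted
    by ``(span_start, span_end)`` within each document.  Construction sorts;
    :meth:`validate` checks the full invariant set.
    """

    name: str
    language: str
    documents: tuple[Document, ...]
    annotations: tuple[Annotation, ...]

    def __init__(
        self,
        name: str,
        language: str,
        documents: Iterable[Document],
        annotations: Iterable[Annotation] = (),
        validate: bool = True,
    ) -> None:
        docs = tuple(documents)
        order = {d.document_id: i for i, d in enumerate(docs)}
        anns = tuple(
            sorted(
                annotations,
                key=lambda a: (order.get(a.document_id, len(order)),) + a.sort_key(),
            )
        )
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "language", language)
        object.__setattr__(self, "documents", docs)
        object.__setattr__(self, "annotations", anns)
        if validate:
            self.validate()

    # -- access helpers -------------------------------------------------

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    @property
    def n_annotations(self) -> int:
        return len(self.annotations)

    @property
    def document_ids(self) -> tuple[str, ...]:
        return tuple(d.document_id for d in self.documents)

    def document(self, document_id: str) -> Document:
        for d in self.documents:
            if d.document_id == document_id:
                return d
        raise KeyError(document_id)

    def annotations_for(self, document_id: str) -> tuple[Annotation, ...]:
        return tuple(a for a in self.annotations if a.document_id == document_id)

    def iter_documents(self) -> Iterator[tuple[Document, tuple[Annotation, ...]]]:
        by_doc: dict[str, list[Annotation]] = {d.document_id: [] for d in self.documents}
        for a in self.annotations:
            by_doc[a.document_id].append(a)
        for d in self.documents:
            yield d, tuple(by_doc[d.document_id])

    # -- invariants ------------------------------------------------------

    def validate(self) -> "AnnotatedCorpus":
        """Check every data-model invariant; raise CorpusValidationError."""
        seen: dict[str, str] = {}
        for d in self.documents:
            if not d.document_id:
                raise CorpusValidationError("empty document_id")
            if d.document_id in seen:
                raise CorpusValidationError(
                    f"duplicate document_id {d.document_id!r}"
                )
            seen[d.document_id] = d.text
        for a in self.annotations:
            if a.document_id not in seen:
                raise CorpusValidationError(
                    f"annotation {a!r} references unknown document "
                    f"{a.document_id!r}"
                )
            if not CUI_PATTERN.match(a.cui):
                raise CorpusValidationError(f"malformed CUI {a.cui!r} in {a!r}")
            text = seen[a.document_id]
            if not (0 <= a.span_start < a.span_end <= len(text)):
                raise CorpusValidationError(
                    f"offsets [{a.span_start}, {a.span_end}) out of range for "
                    f"document {a.document_id!r} of length {len(text)}"
                )
            sliced = text[a.span_start : a.span_end]
            if sliced != a.span_text:
                raise CorpusValidationError(
                    f"span_text mismatch in document {a.document_id!r} at "
                    f"[{a.span_start}, {a.span_end}): expected {a.span_text!r}, "
                    f"text reads {sliced!r}"
                )
        return self

    def with_name(self, name: str) -> "AnnotatedCorpus":
        return AnnotatedCorpus(name, self.language, self.documents, self.annotations,
                               validate=False)


@dataclass(frozen=True)
class CorpusSplit:
    """A train/test partition of a corpus; documents carry their annotations."""

    train: AnnotatedCorpus
    test: AnnotatedCorpus


def split_corpus(
    corpus: AnnotatedCorpus, train_fraction: float, seed: int
) -> CorpusSplit:
    """Randomly partition a corpus into train and test sets by document.

    The train set size is ``train_fraction * n_documents`` rounded to the
    nearest integer (ties up); selection is a seeded uniform shuffle of the
    documents, so the split is deterministic for a fixed seed.  Document
    order within each partition follows the source corpus.
    """
    if corpus.n_documents == 0:
        raise CorpusValidationError("cannot split an empty corpus")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    n = corpus.n_documents
    n_train = int(math.floor(train_fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_ids = {corpus.documents[i].document_id for i in perm[:n_train]}

    def subset(ids: set[str], suffix: str) -> AnnotatedCorpus:
        docs = [d for d in corpus.documents if d.document_id in ids]
        anns = [a for a in corpus.annotations if a.document_id in ids]
        return AnnotatedCorpus(
            f"{corpus.name}-{suffix}", corpus.language, docs, anns, validate=False
        )

    test_ids = set(corpus.document_ids) - train_ids
    return CorpusSplit(train=subset(train_ids, "train"), test=subset(test_ids, "test"))
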