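"""Annotation-preservation quality control.

Quantifies how many annotations survived translation and attributes the
missing ones to two mechanisms:

* **formatting errors** — the translator mangled a marker's brackets, so the
  extraction pattern failed and the CUI string remained in the translated
  text (counted as residual CUIs);
* **pure annotation loss** — the translator dropped the marker entirely
  while keeping the sentence intact, leaving no residual CUI.

Missing counts are computed per document and then summed, so spurious extra
matches in one document never cancel losses in another.  Spurious
annotations (more extracted than original) are tracked separately and never
subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import AnnotatedCorpus
from .errors import MismatchError
from .translate import TranslationProvenance


@dataclass(frozen=True)
class DocumentPreservation:
    """Per-document preservation counts."""

    document_id: str
    n_original: int
    n_extracted: int
    n_formatting_errors: int

    @property
    def n_missing(self) -> int:
        return max(0, self.n_original - self.n_extracted)

    @property
    def n_spurious(self) -> int:
        return max(0, self.n_extracted - self.n_original)

    @property
    def n_pure_loss(self) -> int:
        return max(0, self.n_missing - self.n_formatting_errors)


@dataclass(frozen=True)
class PreservationReport:
    """Corpus-level preservation summary with per-document breakdown."""

    corpus_name: str
    per_document: tuple[DocumentPreservation, ...]

    @property
    def n_original(self) -> int:
        return sum(d.n_original for d in self.per_document)

    @property
    def n_extracted(self) -> int:
        return sum(d.n_extracted for d in self.per_document)

    @property
    def n_missing(self) -> int:
        return sum(d.n_missing for d in self.per_document)

    @property
    def n_spurious(self) -> int:
        return sum(d.n_spurious for d in self.per_document)

    @property
    def n_formatting_errors(self) -> int:
        return sum(d.n_formatting_errors for d in self.per_document)

    @property
    def n_pure_loss(self) -> int:
        return sum(d.n_pure_loss for d in self.per_document)

    @property
    def pct_missing(self) -> float | None:
        """Missing annotations as % of original; None when no originals."""
        if self.n_original == 0:
            return None
        return 100.0 * self.n_missing / self.n_original

    @property
    def pct_formatting_of_missing(self) -> float | None:
        """Formatting errors as % of missing; None when nothing missing."""
        if self.n_missing == 0:
            return None
        return 100.0 * self.n_formatting_errors / self.n_missing

    def to_frame(self) -> pd.DataFrame:
        """Per-document breakdown as a DataFrame (one row per document)."""
        return pd.DataFrame(
            [
                {
                    "document_id": d.document_id,
                    "n_original": d.n_original,
                    "n_extracted": d.n_extracted,
                    "n_missing": d.n_missing,
                    "n_spurious": d.n_spurious,
                    "n_formatting_errors": d.n_formatting_errors,
                    "n_pure_loss": d.n_pure_loss,
                }
                for d in self.per_document
            ]
        )

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)

    def summary_lines(self) -> list[str]:
        pct_miss = "-" if self.pct_missing is None else f"{self.pct_missing:.1f}%"
        pct_fmt = (
            "-" if self.pct_formatting_of_missing is None
            else f"{self.pct_formatting_of_missing:.1f}%"
        )
        return [
            f"Corpus: {self.corpus_name}",
            f"Total no. of annotations: {self.n_original}",
            f"Total no. of missing annotations (% of annotations): "
            f"{self.n_missing} ({pct_miss})",
            f"No. of annotations missing due to formatting errors "
            f"(% of missing annotations): {self.n_formatting_errors} ({pct_fmt})",
            f"No. of annotations missing due to pure loss: {self.n_pure_loss}",
            f"No. of spurious annotations: {self.n_spurious}",
        ]


def preservation_report(
    original: AnnotatedCorpus,
    translated: AnnotatedCorpus,
    provenance: Iterable[TranslationProvenance] = (),
) -> PreservationReport:
    """Compare annotation counts before and after translation.

    ``translated`` must cover a subset of the original's documents; a
    translated document unknown to the original is an error.  Residual-CUI
    counts (formatting-error evidence) are taken from the provenance
    records' extraction results.
    """
    original_ids = set(original.document_ids)
    extra = [i for i in translated.document_ids if i not in original_ids]
    if extra:
        raise MismatchError(
            f"translated documents not present in original corpus: {extra}"
        )
    residual: dict[str, int] = {}
    for p in provenance:
        if p.extraction is not None:
            residual[p.document_id] = p.extraction.residual_cui_count
    orig_counts = {i: 0 for i in original.document_ids}
    for a in original.annotations:
        orig_counts[a.document_id] += 1
    trans_counts = {i: 0 for i in translated.document_ids}
    for a in translated.annotations:
        trans_counts[a.document_id] += 1
    per_doc = tuple(
        DocumentPreservation(
            document_id=doc_id,
            n_original=orig_counts[doc_id],
            n_extracted=trans_counts[doc_id],
            n_formatting_errors=residual.get(doc_id, 0),
        )
        for doc_id in translated.document_ids
    )
    return PreservationReport(corpus_name=translated.name, per_document=per_doc)


@dataclass(frozen=True)
class CorpusCharacteristics:
    """Descriptive statistics of a corpus (document sizes, annotation
    density, optional semantic-type coverage)."""

    n_documents: int
    median_chars_per_document: float | None
    median_annotations_per_document: float | None
    total_annotations: int
    n_unique_semantic_types: int | None = None


def corpus_characteristics(
    corpus: AnnotatedCorpus,
    cui_type_map: Mapping[str, str] | None = None,
) -> CorpusCharacteristics:
    """Compute per-corpus descriptive statistics.

    Medians are over per-document values (documents without annotations
    count as 0 annotations).  The unique-semantic-type count requires a
    user-supplied CUI→semantic-type mapping and is absent otherwise.
    """
    n_docs = corpus.n_documents
    if n_docs == 0:
        return CorpusCharacteristics(0, None, None, 0,
                                     0 if cui_type_map is not None else None)
    chars = [len(d.text) for d in corpus.documents]
    counts = {i: 0 for i in corpus.document_ids}
    for a in corpus.annotations:
        counts[a.document_id] += 1
    n_types: int | None = None
    if cui_type_map is not None:
        n_types = len(
            {cui_type_map[a.cui] for a in corpus.annotations if a.cui in cui_type_map}
        )
    return CorpusCharacteristics(
        n_documents=n_docs,
        median_chars_per_document=float(median(chars)),
        median_annotations_per_document=float(median(counts.values())),
        total_annotations=corpus.n_annotations,
        n_unique_semantic_types=n_types,
    )


def characteristics_table(
    corpora: Mapping[str, AnnotatedCorpus],
    reports: Mapping[str, PreservationReport] | None = None,
    cui_type_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Side-by-side characteristics of several corpora.

    One column per corpus; rows cover document counts, median document
    length, median and total annotation counts, and — for corpora with an
    attached preservation report — missing-annotation and formatting-error
    counts with percentages (one decimal place).
    """
    if not corpora:
        raise ValueError("characteristics_table requires at least one corpus")
    reports = reports or {}
    columns: dict[str, dict[str, object]] = {}
    for cname, corpus in corpora.items():
        ch = corpus_characteristics(corpus, cui_type_map)
        col: dict[str, object] = {
            "No. of documents": ch.n_documents,
            "Median no. of characters per document": ch.median_chars_per_document,
            "Median no. of annotations per document": ch.median_annotations_per_document,
            "Total no. of annotations": ch.total_annotations,
        }
        if ch.n_unique_semantic_types is not None:
            col["No. of unique UMLS semantic types"] = ch.n_unique_semantic_types
        rep = reports.get(cname)
        if rep is not None:
            pct = "-" if rep.pct_missing is None else f"{rep.pct_missing:.1f}%"
            pct_f = (
                "-" if rep.pct_formatting_of_missing is None
                else f"{rep.pct_formatting_of_missing:.1f}%"
            )
            col["Total no. of missing annotations (% of annotations)"] = (
                f"{rep.n_missing} ({pct})"
            )
            col[
                "No. of annotations missing due to formatting errors "
                "(% of missing annotations)"
            ] = f"{rep.n_formatting_errors} ({pct_f})"
        columns[cname] = col
    rows: list[str] = []
    for col in columns.values():
        for key in col:
            if key not in rows:
                rows.append(key)
    return pd.DataFrame(
        {cname: [col.get(r) for r in rows] for cname, col in columns.items()},
        index=rows,
    )
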