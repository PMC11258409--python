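"""Inline marker embedding and extraction of standoff annotations.

The core of the annotation-preserving translation method: before translation
each annotated span is wrapped, in place, in a double-square-bracket marker
carrying its CUI::

    Temporary [[kidney enlargement][C0542518]] in the [[newborn infant][C0021289]]

After translation the markers are located with the extraction pattern
``\\[\\[([^\\]\\[]*)\\]\\[(C[0-9]*)\\]\\]`` and removed, the span text they
carry becomes the new annotation span, and offsets are recomputed against the
cleaned text.  A marker whose brackets were mangled by the translator does
not match the pattern; its CUI then remains in the cleaned text as a
"residual CUI", the observable signature of a formatting error (as opposed to
pure annotation loss, where the whole marker disappears and no CUI is left
behind).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus import Annotation, Document
from .errors import CorpusValidationError, MarkerCollisionError, OverlapError

logger = logging.getLogger(__name__)

#: Extraction pattern, used bit-exact as designed: the span capture forbids
#: square brackets, so mangled or nested markers never match; the CUI capture
#: accepts any digit run after the literal "C".
MARKER_PATTERN = re.compile(r"\[\[([^\]\[]*)\]\[(C[0-9]*)\]\]")

#: Residual-CUI pattern used when counting formatting-error debris in cleaned
#: text.  UMLS CUIs are canonically "C" + 7 digits; requiring exactly 7 at
#: word boundaries avoids false-matching prose tokens like "C3" or gene names.
RESIDUAL_CUI_PATTERN = re.compile(r"(?<!\w)C[0-9]{7}(?!\w)")

_MARKER_SYNTAX = ("[[", "][", "]]")


@dataclass(frozen=True)
class EmbeddedDocument:
    """A document whose annotations have been folded into its text as
    ``[[span][CUI]]`` markers.

    ``excluded`` lists annotations that could not be embedded and were
    dropped on request (overlap pre-filter or bracket-containing spans).
    """

    document_id: str
    embedded_text: str
    excluded: tuple[Annotation, ...] = ()


@dataclass(frozen=True)
class ExtractionResult:
    """Annotations recovered from (translated) marker-embedded text.

    ``clean_text`` is the text with all well-formed marker syntax removed;
    every annotation's offsets index into it.  ``residual_cuis`` are
    CUI-shaped tokens left in the clean text — evidence of markers whose
    brackets were mangled in translation.
    """

    document_id: str
    clean_text: str
    annotations: tuple[Annotation, ...]
    residual_cuis: tuple[str, ...] = ()

    @property
    def residual_cui_count(self) -> int:
        return len(self.residual_cuis)


def _check_overlaps(
    annotations: Sequence[Annotation], on_overlap: str
) -> list[Annotation]:
    """Return annotations sorted by span, handling overlap per policy.

    ``on_overlap="error"`` raises on the first overlapping pair;
    ``"drop-shorter"`` greedily drops the shorter of each overlapping pair
    (the later one on equal length) and logs every drop.
    """
    anns = sorted(annotations, key=lambda a: a.sort_key())
    if on_overlap == "error":
        for prev, cur in zip(anns, anns[1:]):
            if cur.span_start < prev.span_end:
                raise OverlapError(
                    f"overlapping annotations on document "
                    f"{cur.document_id!r}: {prev.cui}@[{prev.span_start},"
                    f"{prev.span_end}) and {cur.cui}@[{cur.span_start},"
                    f"{cur.span_end})"
                )
        return anns
    if on_overlap != "drop-shorter":
        raise ValueError(f"unknown overlap policy {on_overlap!r}")
    kept: list[Annotation] = []
    dropped: list[Annotation] = []
    for cur in anns:
        if kept and cur.span_start < kept[-1].span_end:
            prev = kept[-1]
            if (cur.span_end - cur.span_start) > (prev.span_end - prev.span_start):
                kept[-1] = cur
                dropped.append(prev)
            else:
                dropped.append(cur)
        else:
            kept.append(cur)
    for a in dropped:
        logger.warning(
            "dropping overlapping annotation %s@[%d,%d) on %s",
            a.cui, a.span_start, a.span_end, a.document_id,
        )
    _check_overlaps(kept, "error")
    return kept


def embed_annotations(
    document: Document,
    annotations: Iterable[Annotation],
    on_overlap: str = "error",
    on_collision: str = "error",
) -> EmbeddedDocument:
    """Fold standoff annotations into the document text as inline markers.

    Markers are inserted right-to-left by ``span_start`` so earlier offsets
    stay valid during insertion; stripping the marker syntax recovers the
    original text exactly.  Overlapping annotations cannot be represented
    (the extraction pattern forbids brackets inside a span) and are rejected,
    or pre-filtered with ``on_overlap="drop-shorter"``.  Spans that
    themselves contain marker syntax are likewise unrepresentable; with
    ``on_collision="skip"`` they are excluded and reported instead of
    raising.
    """
    anns: list[Annotation] = []
    excluded: list[Annotation] = []
    for a in annotations:
        if a.document_id != document.document_id:
            raise CorpusValidationError(
                f"annotation {a!r} does not reference document "
                f"{document.document_id!r}"
            )
        if a.span_text != document.text[a.span_start : a.span_end]:
            raise CorpusValidationError(
                f"annotation {a!r} does not match the document text slice"
            )
        if any(tok in a.span_text for tok in _MARKER_SYNTAX):
            if on_collision == "skip":
                excluded.append(a)
                logger.warning(
                    "excluding annotation %s@[%d,%d) on %s: span contains "
                    "marker syntax", a.cui, a.span_start, a.span_end,
                    a.document_id,
                )
                continue
            raise MarkerCollisionError(
                f"span text of {a.cui}@[{a.span_start},{a.span_end}) on "
                f"{a.document_id!r} contains marker syntax and cannot be "
                "embedded"
            )
        anns.append(a)
    kept = _check_overlaps(anns, on_overlap)
    if on_overlap == "drop-shorter":
        excluded.extend(a for a in anns if a not in kept)
    text = document.text
    for a in reversed(kept):
        text = (
            text[: a.span_start]
            + f"[[{a.span_text}][{a.cui}]]"
            + text[a.span_end :]
        )
    return EmbeddedDocument(
        document_id=document.document_id,
        embedded_text=text,
        excluded=tuple(excluded),
    )


def extract_annotations(
    embedded: EmbeddedDocument | str,
    document_id: str | None = None,
    residual_pattern: re.Pattern[str] = RESIDUAL_CUI_PATTERN,
) -> ExtractionResult:
    """Recover standoff annotations from marker-embedded (translated) text.

    Every non-overlapping match of the extraction pattern, scanned left to
    right, yields one annotation: the captured span text stays in place, the
    six bracket characters and the CUI are removed, and the span's offsets
    are recomputed against the cleaned text.  Malformed marker fragments are
    data, not errors — they remain verbatim in the clean text, and any
    CUI-shaped tokens among them are reported as residual CUIs.
    """
    if isinstance(embedded, str):
        embedded = EmbeddedDocument(document_id or "doc", embedded)
    text = embedded.embedded_text
    parts: list[str] = []
    annotations: list[Annotation] = []
    pos = 0
    out_len = 0
    for m in MARKER_PATTERN.finditer(text):
        lead = text[pos : m.start()]
        parts.append(lead)
        out_len += len(lead)
        span, cui = m.group(1), m.group(2)
        annotations.append(
            Annotation(embedded.document_id, cui, out_len, out_len + len(span), span)
        )
        parts.append(span)
        out_len += len(span)
        pos = m.end()
    parts.append(text[pos:])
    clean_text = "".join(parts)
    residual = tuple(m.group(0) for m in residual_pattern.finditer(clean_text))
    return ExtractionResult(
        document_id=embedded.document_id,
        clean_text=clean_text,
        annotations=tuple(annotations),
        residual_cuis=residual,
    )


#: Debris stripper: a residual CUI together with bracket runs touching it,
#: plus one preceding space when present so word spacing stays single.
_DEBRIS_TEMPLATE = r" ?[\[\]]*{cui}[\[\]]*"


def strip_residual_fragments(
    clean_text: str,
    residual_pattern: re.Pattern[str] = RESIDUAL_CUI_PATTERN,
) -> str:
    """Cosmetically remove broken-marker debris from extracted text.

    For each residual CUI the CUI token, any square-bracket runs directly
    adjacent to it, and one preceding space (when present) are deleted, e.g.
    ``"patiënten]][C0030705]]" -> "patiënten"``.  Text containing no residual
    CUIs is returned unchanged.  This cleanup is off by default in the
    pipeline: it is heuristic and loses the evidence that a formatting error
    occurred.
    """
    residuals = {m.group(0) for m in residual_pattern.finditer(clean_text)}
    if not residuals:
        return clean_text
    out = clean_text
    for cui in residuals:
        out = re.sub(_DEBRIS_TEMPLATE.format(cui=re.escape(cui)), "", out)
    return out
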