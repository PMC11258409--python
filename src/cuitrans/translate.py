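"""Translator contract and the annotation-preserving translation pipeline.

A translator is any object mapping text to text given source and target
language tags.  The pipeline embeds each document's annotations as inline
markers, sends the embedded text through the translator, extracts the
annotations from the translated text with recomputed offsets, and assembles
a new corpus in the target language.  Per-document provenance (embedded
source, raw translation, extraction result) is recorded so every preserved
or lost annotation can be audited.

Built-in translators:

* :func:`identity_translator` — returns text unchanged (test double and
  pipeline round-trip oracle);
* :func:`mapping_translator` — replays a fixed source→target table (e.g. a
  previously obtained machine translation);
* :func:`external_adapter` — calls a remote document-translation or chat-LLM
  API over HTTP (declared, exercised only against local stub servers).

The corrupting pseudo-translator with controllable error rates lives in
:mod:`cuitrans.synthetic`.
"""

from __future__ import annotations

import json
import time
import urllib.error
import urllib.request
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Callable, Mapping, Sequence

from .corpus import AnnotatedCorpus, Annotation, Document
from .embedding import EmbeddedDocument, ExtractionResult, embed_annotations, extract_annotations
from .errors import ConfigurationError, CuitransError, TranslatorError

#: Zero-shot system prompt guiding a chat-LLM backend to translate while
#: leaving the inline annotation markers intact.
DEFAULT_SYSTEM_PROMPT = (
    "Translate the document to Dutch (Nederlands). Keep the formatting the "
    "same, including the in-text annotations: [[span][code]]."
)


class Translator(ABC):
    """Pluggable text→text translation contract.

    ``translate`` must return a string for every string input; any backend
    failure is raised as :class:`TranslatorError`.
    """

    name: str = "translator"
    is_deterministic: bool = True

    @abstractmethod
    def translate(
        self,
        text: str,
        source_lang: str = "",
        target_lang: str = "",
        options: Mapping[str, object] | None = None,
    ) -> str:
        ...

    def __call__(self, text: str, source_lang: str = "", target_lang: str = "",
                 options: Mapping[str, object] | None = None) -> str:
        out = self.translate(text, source_lang, target_lang, options)
        if not isinstance(out, str):
            raise TranslatorError(
                f"translator {self.name!r} returned {type(out).__name__}, "
                "expected str"
            )
        return out


class IdentityTranslator(Translator):
    name = "identity"

    def translate(self, text, source_lang="", target_lang="", options=None):
        return text


class MappingTranslator(Translator):
    """Replays a fixed table of known translations; unmapped text passes
    through unchanged."""

    name = "mapping"

    def __init__(self, table: Mapping[str, str]):
        self.table = dict(table)

    def translate(self, text, source_lang="", target_lang="", options=None):
        return self.table.get(text, text)


def identity_translator() -> Translator:
    """Translator returning every input unchanged."""
    return IdentityTranslator()


def mapping_translator(table: Mapping[str, str]) -> Translator:
    """Translator replaying ``table[text]`` when present, else the input."""
    return MappingTranslator(table)


class ExternalApiTranslator(Translator):
    """HTTP adapter for remote translation backends.

    Two backend shapes are supported: a document-translation API
    (``backend: "document-api"``) posting ``{"text", "source_lang",
    "target_lang"}`` and reading ``{"translation": ...}`` back, and a chat
    completion API (``backend: "chat-llm"``) posting a system prompt plus the
    document as the user message and reading
    ``choices[0].message.content``.  Results from remote services are not
    reproducible; ``is_deterministic`` is False and the model/version string
    is recorded in provenance.
    """

    is_deterministic = False

    _BACKENDS = ("document-api", "chat-llm")

    def __init__(self, config: Mapping[str, object]):
        cfg = dict(config)
        backend = cfg.get("backend")
        if backend not in self._BACKENDS:
            raise ConfigurationError(
                f"backend must be one of {self._BACKENDS}, got {backend!r}"
            )
        if not cfg.get("endpoint"):
            raise ConfigurationError("missing 'endpoint' in adapter config")
        if not cfg.get("api_key"):
            raise ConfigurationError("missing 'api_key' in adapter config")
        self.backend: str = str(backend)
        self.endpoint: str = str(cfg["endpoint"])
        self.api_key: str = str(cfg["api_key"])
        self.system_prompt: str = str(cfg.get("system_prompt", DEFAULT_SYSTEM_PROMPT))
        self.model: str = str(cfg.get("model", ""))
        self.temperature = cfg.get("temperature", 0.0)
        self.max_retries = int(cfg.get("max_retries", 2))
        self.timeout = float(cfg.get("timeout", 60.0))
        self.name = f"external-{self.backend}"

    def _payload(self, text: str, source_lang: str, target_lang: str) -> dict:
        if self.backend == "document-api":
            return {"text": text, "source_lang": source_lang,
                    "target_lang": target_lang}
        return {
            "model": self.model,
            "temperature": self.temperature,
            "messages": [
                {"role": "system", "content": self.system_prompt},
                {"role": "user", "content": text},
            ],
        }

    def _parse(self, body: dict) -> str:
        try:
            if self.backend == "document-api":
                return str(body["translation"])
            return str(body["choices"][0]["message"]["content"])
        except (KeyError, IndexError, TypeError) as exc:
            raise TranslatorError(
                f"unexpected response shape from {self.endpoint}: {body!r}"
            ) from exc

    def translate(self, text, source_lang="", target_lang="", options=None):
        payload = json.dumps(self._payload(text, source_lang, target_lang)).encode()
        last: Exception | None = None
        for _attempt in range(self.max_retries + 1):
            req = urllib.request.Request(
                self.endpoint,
                data=payload,
                headers={
                    "Content-Type": "application/json",
                    "Authorization": f"Bearer {self.api_key}",
                },
            )
            try:
                with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                    return self._parse(json.loads(resp.read().decode("utf-8")))
            except (urllib.error.URLError, OSError, json.JSONDecodeError) as exc:
                last = exc
        raise TranslatorError(
            f"translator {self.name!r} failed after {self.max_retries + 1} "
            f"attempts: {last}"
        )


def external_adapter(config: Mapping[str, object]) -> Translator:
    """Build an HTTP translator adapter from a configuration mapping.

    Required keys: ``backend`` (``document-api`` | ``chat-llm``),
    ``endpoint``, ``api_key``.  Optional: ``system_prompt`` (defaults to
    :data:`DEFAULT_SYSTEM_PROMPT`), ``model``, ``temperature``,
    ``max_retries``, ``timeout``.  Configuration errors are raised before
    any network call is made.
    """
    return ExternalApiTranslator(config)


@dataclass(frozen=True)
class TranslationProvenance:
    """Audit record for one document's trip through the pipeline."""

    document_id: str
    embedded_source: str
    raw_translation: str | None
    extraction: ExtractionResult | None
    translator_name: str
    timestamp: str
    error: str | None = None


def _split_paragraph_chunks(text: str) -> list[str]:
    """Split embedded text at blank lines that fall outside markers,
    keeping the separators so re-joining is exact concatenation."""
    from .embedding import MARKER_PATTERN

    marker_spans = [(m.start(), m.end()) for m in MARKER_PATTERN.finditer(text)]

    def inside_marker(i: int) -> bool:
        return any(s <= i < e for s, e in marker_spans)

    chunks: list[str] = []
    start = 0
    i = 0
    while i < len(text) - 1:
        if text[i] == "\n" and text[i + 1] == "\n" and not inside_marker(i):
            chunks.append(text[start : i + 2])
            start = i + 2
            i += 2
        else:
            i += 1
    chunks.append(text[start:])
    return [c for c in chunks if c]


def translate_corpus(
    corpus: AnnotatedCorpus,
    translator: Translator,
    target_lang: str,
    source_lang: str | None = None,
    on_overlap: str = "error",
    chunk_paragraphs: bool = False,
    name: str | None = None,
) -> tuple[AnnotatedCorpus, list[TranslationProvenance]]:
    """Translate a corpus document by document, preserving annotations.

    For each document: embed → translate → extract.  The output corpus has
    the same document ids, ``language = target_lang``, and the annotations
    recovered from the translated text.  Documents whose translator call
    fails are excluded from the output corpus and reported via a provenance
    record with ``error`` set — never silently dropped.  Embedding errors
    (overlaps, marker collisions) are raised with document context since
    they indicate an invalid input corpus rather than a translation failure.

    ``chunk_paragraphs`` translates each blank-line-separated paragraph in a
    separate call (for length-limited backends) and re-joins the results.
    """
    src = source_lang if source_lang is not None else corpus.language
    out_docs: list[Document] = []
    out_anns: list[Annotation] = []
    provenance: list[TranslationProvenance] = []
    for document, annotations in corpus.iter_documents():
        try:
            embedded = embed_annotations(document, annotations, on_overlap=on_overlap)
        except CuitransError as exc:
            raise type(exc)(f"document {document.document_id!r}: {exc}") from exc
        stamp = datetime.now(timezone.utc).isoformat()
        options = {"document_id": document.document_id}
        try:
            if chunk_paragraphs:
                raw = "".join(
                    translator(c, src, target_lang, options)
                    for c in _split_paragraph_chunks(embedded.embedded_text)
                )
            else:
                raw = translator(embedded.embedded_text, src, target_lang, options)
        except TranslatorError as exc:
            provenance.append(
                TranslationProvenance(
                    document_id=document.document_id,
                    embedded_source=embedded.embedded_text,
                    raw_translation=None,
                    extraction=None,
                    translator_name=translator.name,
                    timestamp=stamp,
                    error=str(exc),
                )
            )
            continue
        extraction = extract_annotations(
            EmbeddedDocument(document.document_id, raw)
        )
        out_docs.append(Document(document.document_id, extraction.clean_text))
        out_anns.extend(extraction.annotations)
        provenance.append(
            TranslationProvenance(
                document_id=document.document_id,
                embedded_source=embedded.embedded_text,
                raw_translation=raw,
                extraction=extraction,
                translator_name=translator.name,
                timestamp=stamp,
            )
        )
    out = AnnotatedCorpus(
        name if name is not None else f"{corpus.name}-{translator.name}",
        target_lang,
        out_docs,
        out_anns,
    )
    return out, provenance
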