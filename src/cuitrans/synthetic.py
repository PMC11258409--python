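"""Synthetic annotated corpora and corrupting pseudo-translators.

The generator produces corpora of pseudo-word documents with non-overlapping
CUI-annotated spans at a controllable annotation density, emulating the two
regimes seen in real concept-annotated corpora: biomedical-abstract-style
collections of many short, densely annotated documents, and clinical-note
collections of fewer, much longer, sparsely annotated documents.  The text
is deliberately not linguistically realistic: its job is to carry spans with
exactly known offsets.

The corrupting pseudo-translator damages marker-embedded text with known,
logged error rates, reproducing the two failure modes observed with real
machine-translation services:

* **annotation loss** — the whole ``[[span][CUI]]`` construct is replaced by
  its bare span text (the sentence survives, the annotation vanishes);
* **formatting error** — the ``][`` separator is mangled to ``]][`` so the
  extraction pattern cannot match while the CUI string stays in the text.

It can also swap adjacent tokens and substitute words *outside* markers to
emulate translation-induced rewording.  Because corruption operates only on
marker constructs and inter-marker tokens, every preservation failure in a
corrupted corpus is injected, never incidental — the injection log is exact
ground truth for the preservation-QC report.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import AnnotatedCorpus, Annotation, Document
from .embedding import MARKER_PATTERN
from .errors import ConfigurationError
from .translate import Translator, translate_corpus
from .preservation import preservation_report

_LETTERS = np.array(list(string.ascii_lowercase))


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic corpus generator.

    ``annotation_density`` is the expected number of annotated spans per
    document (Poisson); it must leave room in the document, i.e. stay below
    half the expected token count.
    """

    n_documents: int = 100
    mean_sentences_per_document: float = 6.0
    tokens_per_sentence: tuple[int, int] = (6, 14)
    annotation_density: float = 8.0
    n_concepts: int = 50
    concept_lexicon: Mapping[str, str] | None = None
    seed: int = 0
    name: str = "synthetic"
    language: str = "en"


def medmentions_like(seed: int = 0, n_documents: int = 100) -> GeneratorConfig:
    """Short, densely annotated documents (abstract-like regime)."""
    return GeneratorConfig(
        n_documents=n_documents,
        mean_sentences_per_document=8.0,
        annotation_density=20.0,
        n_concepts=120,
        seed=seed,
        name="synthetic-dense",
    )


def shareclef_like(seed: int = 0, n_documents: int = 30) -> GeneratorConfig:
    """Long, sparsely annotated documents (clinical-note regime)."""
    return GeneratorConfig(
        n_documents=n_documents,
        mean_sentences_per_document=60.0,
        annotation_density=8.0,
        n_concepts=60,
        seed=seed,
        name="synthetic-sparse",
    )


def _random_word(rng: np.random.Generator) -> str:
    length = int(rng.integers(3, 10))
    return "".join(rng.choice(_LETTERS, size=length))


def make_lexicon(n_concepts: int, rng: np.random.Generator) -> dict[str, str]:
    """Generate ``n_concepts`` unique bracket-free pseudo-terms with unique
    7-digit CUIs."""
    cuis = rng.choice(np.arange(1, 10_000_000), size=n_concepts, replace=False)
    lexicon: dict[str, str] = {}
    i = 0
    while len(lexicon) < n_concepts:
        n_words = 1 + int(rng.random() < 0.35)
        term = " ".join(_random_word(rng) for _ in range(n_words))
        if term not in lexicon:
            lexicon[term] = f"C{int(cuis[i]):07d}"
            i += 1
    return lexicon


def generate_corpus(config: GeneratorConfig) -> AnnotatedCorpus:
    """Generate a validated synthetic annotated corpus.

    Deterministic for a fixed seed.  Documents are sentences of random
    pseudo-words; annotated spans are lexicon terms substituted for single
    tokens, so spans never overlap and always satisfy the slice invariant.
    """
    if config.n_documents < 0:
        raise ConfigurationError("n_documents must be non-negative")
    lo, hi = config.tokens_per_sentence
    expected_tokens = config.mean_sentences_per_document * (lo + hi) / 2.0
    if config.annotation_density > 0.5 * expected_tokens:
        raise ConfigurationError(
            f"annotation density {config.annotation_density} incompatible "
            f"with expected document length (~{expected_tokens:.0f} tokens)"
        )
    rng = np.random.default_rng(config.seed)
    lexicon = (
        dict(config.concept_lexicon)
        if config.concept_lexicon is not None
        else make_lexicon(config.n_concepts, rng)
    )
    terms = list(lexicon)
    documents: list[Document] = []
    annotations: list[Annotation] = []
    for d in range(config.n_documents):
        doc_id = f"doc{d:05d}"
        n_sent = max(1, int(rng.poisson(config.mean_sentences_per_document)))
        sentences = [
            [_random_word(rng) for _ in range(int(rng.integers(lo, hi + 1)))]
            for _ in range(n_sent)
        ]
        flat: list[tuple[int, int]] = [
            (si, ti) for si, s in enumerate(sentences) for ti in range(len(s))
        ]
        n_ann = min(int(rng.poisson(config.annotation_density)), len(flat) // 2)
        slot_idx = rng.choice(len(flat), size=n_ann, replace=False)
        chosen: dict[tuple[int, int], str] = {}
        for k in slot_idx:
            term = terms[int(rng.integers(len(terms)))]
            chosen[flat[int(k)]] = term
        # assemble text sentence by sentence, tracking span offsets
        pieces: list[str] = []
        offset = 0
        for si, sent in enumerate(sentences):
            for ti, tok in enumerate(sent):
                word = chosen.get((si, ti), tok)
                if (si, ti) in chosen:
                    annotations.append(
                        Annotation(
                            doc_id,
                            lexicon[word],
                            offset,
                            offset + len(word),
                            word,
                        )
                    )
                pieces.append(word)
                offset += len(word)
                last_in_sentence = ti == len(sent) - 1
                sep = ". " if last_in_sentence and si < n_sent - 1 else (
                    "." if last_in_sentence else " "
                )
                pieces.append(sep)
                offset += len(sep)
        documents.append(Document(doc_id, "".join(pieces)))
    return AnnotatedCorpus(config.name, config.language, documents, annotations)


@dataclass(frozen=True)
class CorruptionConfig:
    """Error rates of the corrupting pseudo-translator.

    Per marker, corruption modes are disjoint: a marker is lost (probability
    ``loss_rate``), bracket-mangled (``format_error_rate``), or left intact.
    ``token_shuffle_rate`` swaps adjacent token pairs outside markers and
    ``substitution_map`` rewrites non-marker tokens, emulating rewording.
    """

    loss_rate: float = 0.0
    format_error_rate: float = 0.0
    token_shuffle_rate: float = 0.0
    substitution_map: Mapping[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("loss_rate", "format_error_rate", "token_shuffle_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.loss_rate + self.format_error_rate > 1.0:
            raise ConfigurationError(
                "loss_rate + format_error_rate must not exceed 1"
            )


@dataclass(frozen=True)
class InjectionRecord:
    """Ground-truth log entry for one injected corruption."""

    document_id: str
    cui: str
    kind: str  # "loss" | "format_error"


class CorruptingTranslator(Translator):
    """Pseudo-translator injecting marker corruptions at known rates.

    Every injection is appended to :attr:`injection_log` with the document
    id (taken from the call's ``options``) and the affected CUI, so measured
    preservation errors can be compared against exact ground truth.
    Deterministic for a fixed config seed and call sequence.
    """

    name = "corrupting"
    is_deterministic = True

    def __init__(self, config: CorruptionConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.injection_log: list[InjectionRecord] = []

    def reset(self) -> None:
        self.rng = np.random.default_rng(self.config.seed)
        self.injection_log = []

    def _mutate_segment(self, segment: str) -> str:
        cfg = self.config
        if cfg.token_shuffle_rate == 0.0 and not cfg.substitution_map:
            return segment
        tokens = segment.split(" ")
        if cfg.substitution_map:
            tokens = [cfg.substitution_map.get(t, t) for t in tokens]
        i = 0
        while i < len(tokens) - 1:
            if self.rng.random() < cfg.token_shuffle_rate:
                tokens[i], tokens[i + 1] = tokens[i + 1], tokens[i]
                i += 2
            else:
                i += 1
        return " ".join(tokens)

    def translate(self, text, source_lang="", target_lang="", options=None):
        document_id = str((options or {}).get("document_id", ""))
        cfg = self.config
        out: list[str] = []
        pos = 0
        for m in MARKER_PATTERN.finditer(text):
            out.append(self._mutate_segment(text[pos : m.start()]))
            span, cui = m.group(1), m.group(2)
            u = self.rng.random()
            if u < cfg.loss_rate:
                out.append(span)
                self.injection_log.append(InjectionRecord(document_id, cui, "loss"))
            elif u < cfg.loss_rate + cfg.format_error_rate:
                out.append(f"[[{span}]][{cui}]]")
                self.injection_log.append(
                    InjectionRecord(document_id, cui, "format_error")
                )
            else:
                out.append(m.group(0))
            pos = m.end()
        out.append(self._mutate_segment(text[pos:]))
        return "".join(out)


def corrupting_translator(config: CorruptionConfig) -> CorruptingTranslator:
    """Build a corrupting pseudo-translator with logged injections."""
    return CorruptingTranslator(config)


def recovery_experiment(
    gen: GeneratorConfig,
    corr: CorruptionConfig,
    n_seeds: int = 1,
) -> pd.DataFrame:
    """Generate → corrupt → measure, comparing QC output to ground truth.

    For each of ``n_seeds`` replicates (seeds offset from the configs'
    seeds), a synthetic corpus is generated, pushed through the
    annotation-preserving pipeline with a corrupting translator, and
    summarized by :func:`cuitrans.preservation.preservation_report`.  The
    returned table holds, per seed, the injected loss/formatting counts from
    the translator's log next to the measured ``n_missing`` /
    ``n_formatting_errors`` / ``n_pure_loss``; with the deterministic
    injector the measured counts equal the injected counts exactly.
    """
    if n_seeds < 1:
        raise ConfigurationError("n_seeds must be >= 1")
    rows = []
    for i in range(n_seeds):
        g = replace(gen, seed=gen.seed + i)
        c = replace(corr, seed=corr.seed + i)
        corpus = generate_corpus(g)
        translator = corrupting_translator(c)
        translated, provenance = translate_corpus(corpus, translator, "xx")
        report = preservation_report(corpus, translated, provenance)
        injected_loss = sum(
            1 for r in translator.injection_log if r.kind == "loss"
        )
        injected_format = sum(
            1 for r in translator.injection_log if r.kind == "format_error"
        )
        rows.append(
            {
                "seed": g.seed,
                "n_annotations": corpus.n_annotations,
                "injected_loss": injected_loss,
                "injected_format_errors": injected_format,
                "n_missing": report.n_missing,
                "n_formatting_errors": report.n_formatting_errors,
                "n_pure_loss": report.n_pure_loss,
                "exact_recovery": (
                    report.n_missing == injected_loss + injected_format
                    and report.n_formatting_errors == injected_format
                    and report.n_pure_loss == injected_loss
                ),
            }
        )
    return pd.DataFrame(rows)
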