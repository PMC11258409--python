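"""Translation similarity metrics: BLEU, chrF, and pairwise corpus agreement.

Both metrics are computed per document on the 0–1 scale and summarized over
a corpus pair as mean ± standard deviation.

BLEU here is document-level: the geometric mean of modified n-gram
precisions up to ``max_order`` multiplied by the brevity penalty
``min(1, exp(1 - ref_len/hyp_len))``.  Tokenization is whitespace splitting
after separating punctuation from words; no lowercasing.  When an order has
zero matching n-grams the add-one smoothing (default) replaces the count
with ``(matches + 1) / (total + 1)``; a hypothesis sharing no unigrams with
the reference scores 0 regardless of smoothing.

chrF is the F_beta (beta = 2 by default, weighting recall) over character
n-gram precision and recall averaged across orders 1..``char_order``, with
whitespace removed before n-gram extraction.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .corpus import AnnotatedCorpus
from .errors import MismatchError

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)
_WS_RE = re.compile(r"\s+")


def tokenize(text: str) -> list[str]:
    """Split punctuation from words, then whitespace-tokenize."""
    return _TOKEN_RE.findall(text)


def _ngram_counts(items: Sequence, n: int) -> Counter:
    return Counter(tuple(items[i : i + n]) for i in range(len(items) - n + 1))


def bleu(
    hypothesis: str,
    reference: str,
    max_order: int = 4,
    smoothing: str = "add1",
) -> float:
    """Document-level BLEU in [0, 1].

    ``smoothing`` is ``"add1"`` (add-one on n-gram counts for orders with
    zero matches) or ``"none"`` (zero matches at any order give score 0).
    Both strings empty scores 1.0; exactly one empty scores 0.0.
    """
    if smoothing not in ("add1", "none"):
        raise ValueError(f"unknown smoothing policy {smoothing!r}")
    hyp = tokenize(hypothesis)
    ref = tokenize(reference)
    if not hyp and not ref:
        return 1.0
    if not hyp or not ref:
        return 0.0
    log_precisions: list[float] = []
    for n in range(1, max_order + 1):
        hyp_counts = _ngram_counts(hyp, n)
        total = sum(hyp_counts.values())
        if total == 0:
            # hypothesis shorter than n tokens: order carries no information
            continue
        ref_counts = _ngram_counts(ref, n)
        matches = sum(min(c, ref_counts[g]) for g, c in hyp_counts.items())
        if n == 1 and matches == 0:
            return 0.0
        if matches == 0:
            if smoothing == "none":
                return 0.0
            p = (matches + 1) / (total + 1)
        else:
            p = matches / total
        log_precisions.append(math.log(p))
    if not log_precisions:
        return 0.0
    brevity = 1.0 if len(hyp) >= len(ref) else math.exp(1.0 - len(ref) / len(hyp))
    return brevity * math.exp(sum(log_precisions) / len(log_precisions))


def chrf(
    hypothesis: str,
    reference: str,
    char_order: int = 6,
    beta: float = 2.0,
    include_word_ngrams: bool = False,
) -> float:
    """Character n-gram F-score in [0, 1].

    Precision and recall of character n-grams (whitespace removed) are
    averaged over orders 1..``char_order`` and combined as F_beta.  With
    ``include_word_ngrams`` word uni- and bigram precision/recall join the
    average (chrF++-style).  Orders where neither side has n-grams are
    skipped; both strings empty scores 1.0, exactly one empty 0.0.
    """
    hyp_chars = _WS_RE.sub("", hypothesis)
    ref_chars = _WS_RE.sub("", reference)
    if not hyp_chars and not ref_chars:
        return 1.0
    if not hyp_chars or not ref_chars:
        return 0.0
    precisions: list[float] = []
    recalls: list[float] = []

    def add_order(hyp_seq: Sequence, ref_seq: Sequence, n: int) -> None:
        hyp_counts = _ngram_counts(hyp_seq, n)
        ref_counts = _ngram_counts(ref_seq, n)
        hyp_total = sum(hyp_counts.values())
        ref_total = sum(ref_counts.values())
        if hyp_total == 0 and ref_total == 0:
            return
        matches = sum(min(c, ref_counts[g]) for g, c in hyp_counts.items())
        precisions.append(matches / hyp_total if hyp_total else 0.0)
        recalls.append(matches / ref_total if ref_total else 0.0)

    for n in range(1, char_order + 1):
        add_order(hyp_chars, ref_chars, n)
    if include_word_ngrams:
        hyp_words = tokenize(hypothesis)
        ref_words = tokenize(reference)
        for n in (1, 2):
            add_order(hyp_words, ref_words, n)
    avg_p = sum(precisions) / len(precisions)
    avg_r = sum(recalls) / len(recalls)
    denom = beta * beta * avg_p + avg_r
    if denom == 0.0:
        return 0.0
    return (1 + beta * beta) * avg_p * avg_r / denom


@dataclass(frozen=True)
class AgreementSummary:
    """Mean ± SD of one per-document similarity metric over a corpus pair."""

    metric: str
    mean: float
    sd: float
    n_documents: int
    per_document_scores: tuple[float, ...]


def _summarize(metric: str, scores: Sequence[float]) -> AgreementSummary:
    arr = np.asarray(scores, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return AgreementSummary(
        metric=metric,
        mean=float(arr.mean()),
        sd=sd,
        n_documents=arr.size,
        per_document_scores=tuple(float(s) for s in arr),
    )


def pairwise_agreement(
    corpus_a: AnnotatedCorpus,
    corpus_b: AnnotatedCorpus,
    max_order: int = 4,
    char_order: int = 6,
    smoothing: str = "add1",
) -> list[AgreementSummary]:
    """Per-document BLEU and chrF between two corpora, as mean ± SD.

    The corpora must share their document-id set; plain texts are compared
    (``corpus_a`` as hypothesis, ``corpus_b`` as reference), annotations are
    ignored.
    """
    ids_a = set(corpus_a.document_ids)
    ids_b = set(corpus_b.document_ids)
    if ids_a != ids_b:
        raise MismatchError(
            "document-id sets differ; symmetric difference: "
            f"{sorted(ids_a ^ ids_b)}"
        )
    bleu_scores: list[float] = []
    chrf_scores: list[float] = []
    for doc in corpus_a.documents:
        other = corpus_b.document(doc.document_id)
        bleu_scores.append(bleu(doc.text, other.text, max_order=max_order,
                                smoothing=smoothing))
        chrf_scores.append(chrf(doc.text, other.text, char_order=char_order))
    return [_summarize("bleu", bleu_scores), _summarize("chrf", chrf_scores)]
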