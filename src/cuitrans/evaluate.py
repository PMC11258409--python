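"""Strict-span concept-extraction evaluation.

A predicted concept is correct only if its CUI *and* its exact character
span (start and end) match an annotation in the reference; matching is
one-to-one.  Unmatched predictions are false positives, unmatched reference
annotations false negatives.  Precision, recall and F1 use the 0/0 → 0
convention so aggregate tables always total.

For cross-corpus comparison, metric values are mean-centered per corpus
(subtracting each corpus's mean metric value), and group differences are
assessed with Bonferroni-adjusted two-sided Wilcoxon tests (rank-sum for
independent groups — the default — or signed-rank when paired).

A toy longest-match dictionary extractor is included so the evaluator can
be exercised end to end without any external NLP tooling.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .corpus import AnnotatedCorpus, Annotation

#: Sample-size bound below which scipy uses the exact permutation null for
#: the rank-sum / signed-rank statistic (ties force the tie-corrected
#: normal approximation instead).
EXACT_THRESHOLD = 8


@dataclass(frozen=True)
class EvalMetrics:
    """Counts and derived scores for one evaluation run."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def _spans_overlap(a: Annotation, b: Annotation) -> bool:
    return a.span_start < b.span_end and b.span_start < a.span_end


def evaluate_strict(
    reference: Iterable[Annotation],
    predicted: Iterable[Annotation],
    corpus: AnnotatedCorpus | None = None,
    mode: str = "strict",
) -> EvalMetrics:
    """Score predictions against reference annotations.

    In ``strict`` mode (the headline setting) a true positive requires an
    exact ``(document_id, cui, span_start, span_end)`` match, one-to-one.
    The exploratory ``overlap`` mode relaxes location to any span overlap
    with the same CUI, matched greedily in ``(document, start, end, cui)``
    order.  When ``corpus`` is given, predictions are validated against its
    documents first.
    """
    ref = sorted(reference, key=lambda a: (a.document_id,) + a.sort_key())
    pred = sorted(predicted, key=lambda a: (a.document_id,) + a.sort_key())
    if corpus is not None:
        AnnotatedCorpus(corpus.name, corpus.language, corpus.documents, pred)
    if mode == "strict":
        ref_counts = Counter(
            (a.document_id, a.cui, a.span_start, a.span_end) for a in ref
        )
        tp = 0
        for a in pred:
            key = (a.document_id, a.cui, a.span_start, a.span_end)
            if ref_counts[key] > 0:
                ref_counts[key] -= 1
                tp += 1
    elif mode == "overlap":
        unmatched = list(ref)
        tp = 0
        for p in pred:
            for i, r in enumerate(unmatched):
                if (
                    r.document_id == p.document_id
                    and r.cui == p.cui
                    and _spans_overlap(r, p)
                ):
                    del unmatched[i]
                    tp += 1
                    break
    else:
        raise ValueError(f"unknown matching mode {mode!r}")
    return EvalMetrics(tp=tp, fp=len(pred) - tp, fn=len(ref) - tp)


def dictionary_extractor(
    corpus: AnnotatedCorpus,
    lexicon: Mapping[str, str],
    case_sensitive: bool = False,
) -> list[Annotation]:
    """Longest-match left-to-right dictionary concept extractor.

    Scans each document for lexicon terms at word boundaries; at each
    position the longest matching term wins and matches never overlap.
    Intended as an in-repo stand-in extractor for exercising the evaluator,
    not as a serious NER system.
    """
    if not lexicon:
        return []
    for term in lexicon:
        if any(ch in term for ch in "[]"):
            raise ValueError(f"lexicon term {term!r} contains bracket characters")
    terms = sorted(lexicon, key=len, reverse=True)
    pattern = re.compile(
        r"(?<!\w)(?:" + "|".join(re.escape(t) for t in terms) + r")(?!\w)",
        0 if case_sensitive else re.IGNORECASE,
    )
    lookup = {t if case_sensitive else t.lower(): cui for t, cui in lexicon.items()}
    out: list[Annotation] = []
    for doc in corpus.documents:
        for m in pattern.finditer(doc.text):
            key = m.group(0) if case_sensitive else m.group(0).lower()
            out.append(
                Annotation(doc.document_id, lookup[key], m.start(), m.end(), m.group(0))
            )
    return out


def mean_center(results: pd.DataFrame, value_column: str = "value") -> pd.DataFrame:
    """Center metric values by corpus.

    ``results`` must contain at least the columns ``corpus``, ``metric`` and
    ``value``; a ``centered`` column is added holding
    ``value − mean(value | corpus, metric)``, so each (corpus, metric)
    group's centered mean is 0 and within-group differences are unchanged.
    """
    if len(results) == 0:
        raise ValueError("mean_center requires a non-empty results table")
    for col in ("corpus", "metric", value_column):
        if col not in results.columns:
            raise ValueError(f"results table lacks required column {col!r}")
    out = results.copy()
    out["centered"] = out[value_column] - out.groupby(["corpus", "metric"])[
        value_column
    ].transform("mean")
    return out


@dataclass(frozen=True)
class PairwiseTest:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class ComparisonResult:
    """All pairwise Wilcoxon comparisons between named groups."""

    labels: tuple[str, ...]
    comparisons: tuple[PairwiseTest, ...]
    alpha: float
    paired: bool

    @property
    def n_comparisons(self) -> int:
        return len(self.comparisons)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_a": c.group_a,
                    "group_b": c.group_b,
                    "statistic": c.statistic,
                    "p_raw": c.p_raw,
                    "p_adjusted": c.p_adjusted,
                    "significant": c.significant,
                }
                for c in self.comparisons
            ]
        )


def wilcoxon_bonferroni(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.01,
    paired: bool = False,
) -> ComparisonResult:
    """All-pairs two-sided Wilcoxon tests with Bonferroni adjustment.

    Unpaired (default) uses the rank-sum (Mann-Whitney U) test, paired the
    signed-rank test on aligned observations.  The exact permutation null is
    used for small untied samples (both n < ``EXACT_THRESHOLD``), the
    tie-corrected normal approximation otherwise.  Each raw p-value is
    multiplied by the number of pairwise tests and capped at 1; a pair is
    flagged significant when the adjusted p is below ``alpha``.
    """
    data = {k: list(map(float, v)) for k, v in groups.items()}
    for label, values in data.items():
        if len(values) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 observations")
    labels = tuple(data)
    pairs = list(combinations(labels, 2))
    results: list[PairwiseTest] = []
    for a, b in pairs:
        x, y = data[a], data[b]
        if paired:
            if len(x) != len(y):
                raise ValueError(
                    f"paired test requires equal group sizes: {a!r} has "
                    f"{len(x)}, {b!r} has {len(y)}"
                )
            if all(xi == yi for xi, yi in zip(x, y)):
                stat, p = 0.0, 1.0
            else:
                res = stats.wilcoxon(x, y, alternative="two-sided", method="auto")
                stat, p = float(res.statistic), float(res.pvalue)
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
            stat, p = float(res.statistic), float(res.pvalue)
        results.append(PairwiseTest(a, b, stat, p, min(1.0, p * len(pairs)), False))
    adjusted = tuple(
        PairwiseTest(
            c.group_a, c.group_b, c.statistic, c.p_raw, c.p_adjusted,
            c.p_adjusted < alpha,
        )
        for c in results
    )
    return ComparisonResult(
        labels=labels, comparisons=adjusted, alpha=alpha, paired=paired
    )
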