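# Methods

## The annotation-preservation model

A corpus is a set of documents plus standoff annotations
`(DocumentId, CUI, SpanStart, SpanEnd, SpanText)`.  Offsets are 0-based,
end-exclusive, and counted in Unicode code points — never bytes — and the
package enforces the slice invariant `text[start:end] == span_text` on
every read, construction and extraction.  Text is never normalized (no NFC,
no whitespace collapsing) anywhere in the pipeline, because any mutation of
the text silently invalidates offsets.

Embedding rewrites each annotated span in place as `[[span][CUI]]`.
Markers are inserted right-to-left by `span_start`, so earlier offsets stay
valid during insertion and no bookkeeping is needed.  Two classes of
annotations cannot be represented by this grammar and are rejected up
front:

- **overlapping spans** (equal, nested or crossing): the extraction
  pattern's span capture `[^\]\[]*` forbids brackets inside a span, so
  nested markers could never be re-extracted.  An optional pre-filter
  (`on_overlap="drop-shorter"`) drops the shorter of each overlapping pair,
  logging every drop, for corpora that contain nested annotations;
- **spans containing marker syntax** (`[[`, `][`, `]]`): optionally
  excluded-and-reported (`on_collision="skip"`) instead of raising.

Extraction applies the pattern `\[\[([^\]\[]*)\]\[(C[0-9]*)\]\]` exactly as
designed — including the permissive `C[0-9]*` CUI capture — scanning left
to right.  Matched marker syntax is removed, captured spans stay in place,
offsets are recomputed against the cleaned text.  Anything that does not
match is data, not an error: mangled fragments remain verbatim in the clean
text.

**Residual CUIs.**  A marker whose brackets were mangled in translation
(e.g. `[[patiënten]][C0030705]]`) fails the pattern, so its annotation is
lost *and* its CUI string stays in the text.  Counting these CUI-shaped
leftovers is how formatting errors are distinguished from pure annotation
loss (marker dropped entirely, no trace).  The residual counter uses
`C[0-9]{7}` at word boundaries rather than the extraction pattern's
`C[0-9]*`: UMLS CUIs are canonically 7-digit, and a looser pattern would
false-match prose tokens ("C3", catalog numbers) when counting debris.  The
pattern is a parameter of `extract_annotations`.

`strip_residual_fragments` removes a residual CUI plus bracket runs
directly adjacent to it plus one preceding space.  It is off by default:
it is a cosmetic heuristic, and it destroys the evidence the QC report
counts.  Published translated corpora in this workflow retain the debris.

## The translation pipeline

`translate_corpus` runs embed → translate → extract per document and
assembles the target-language corpus, recording per-document provenance
(embedded source, raw translation, extraction result, translator name,
timestamp).  Documents whose translator call fails are excluded from the
output and reported via a provenance record with `error` set.  Translation
granularity is one document per call; `chunk_paragraphs=True` splits at
blank lines falling outside markers for length-limited backends and
re-joins by exact concatenation.

The external HTTP adapter supports a document-translation API shape and a
chat-completion shape (zero-shot system prompt: *"Translate the document to
Dutch (Nederlands). Keep the formatting the same, including the in-text
annotations: [[span][code]]."* — replaceable per config).  Chunking and
temperature defaults (off / 0.0) are the package's own choices and are
recorded in the run manifest.  The adapter is exercised only against local
stub servers in the test suite; remote backends are declared
non-deterministic and their model strings belong in provenance.

## Preservation QC

Per document: `n_missing = max(0, n_original − n_extracted)`,
`n_formatting_errors` = residual-CUI count from the extraction,
`n_pure_loss = max(0, n_missing − n_formatting_errors)`.  Corpus totals are
sums of per-document values, *not* differences of corpus totals — a
document with spurious extra matches must never cancel losses elsewhere.
Spurious annotations (extracted > original) are tracked separately and
never subtracted.  Percentages (missing as % of source-corpus annotations;
formatting errors as % of missing) are printed to one decimal place; raw
counts are always retained.  Documents absent from the translated corpus
(excluded failures) are outside the report's denominator.

## Translation metrics

BLEU and chrF are computed per document on the 0–1 scale and summarized
over a corpus pair as mean ± sample SD, because per-corpus SD columns
require document-level scores.

- **BLEU**: geometric mean of modified n-gram precisions, orders 1–4, times
  the brevity penalty `min(1, exp(1 − ref_len/hyp_len))`.  Tokenization:
  punctuation split from words, whitespace tokens, no lowercasing.
  Default smoothing is add-one on n-gram counts for orders with zero
  matches (switchable to `"none"`); a hypothesis sharing no unigrams with
  the reference scores 0 regardless of smoothing, so disjoint texts score
  exactly 0.  Orders longer than the hypothesis are skipped.  Both strings
  empty → 1.0; exactly one empty → 0.0.
- **chrF**: F_β (β = 2, recall-weighted) over character n-gram precision
  and recall averaged across orders 1–6, whitespace removed before n-gram
  extraction; optional word uni/bigrams (off by default).  Orders with no
  n-grams on either side are skipped.

These choices are fixed, documented defaults; BLEU/chrF variants differ
across implementations and the variant in use must be stated when
reporting.

## Extraction evaluation

Strict matching: a prediction is a true positive iff an unmatched reference
annotation has the identical `(document_id, cui, span_start, span_end)`;
matching is one-to-one, ties broken by input order after sorting by
(document, start, end, cui) for determinism.  Precision, recall and F1 use
the 0/0 → 0 convention so aggregate tables always total; this penalizes
empty predictions rather than leaving cells undefined.  A relaxed mode
(same CUI, any span overlap) exists behind a flag for exploration and is
never used in headline outputs.

Cross-corpus comparison subtracts each (corpus, metric) group's mean from
its values (mean-centering), making model effects comparable across corpora
of very different difficulty; centering is shift-only, so within-group
differences are untouched.  Group differences are tested with all-pairs
two-sided Wilcoxon tests — rank-sum for independent groups (the default,
since the centered values are compared as distributions), signed-rank when
a pairing is declared — with exact permutation nulls for untied samples
below n = 8 and the tie-corrected normal approximation otherwise, and
Bonferroni adjustment `p_adj = min(1, p · #pairs)` at α = 0.01.

## Synthetic data: what it emulates, what it does not

The generator produces documents of random pseudo-word sentences with
lexicon terms (1–2 pseudo-words, unique 7-digit CUIs) substituted at
randomly chosen token slots, so annotations are non-overlapping and satisfy
the slice invariant by construction.  Annotation counts per document are
Poisson with mean `annotation_density`; a density above half the expected
token count is rejected.  Two presets mirror the corpus regimes that matter
for this method, scaled to roughly a quarter of the real corpora's size so
the full suite runs in seconds: `medmentions_like` (short documents, ~20
annotations each — the dense-abstract regime) and `shareclef_like` (long
documents, ~8 annotations — the sparse-clinical-note regime).

The corrupting pseudo-translator damages the embedded text at configured
per-marker rates, modes disjoint per marker: **loss** replaces the whole
marker with its bare span text; **format error** rewrites the separator to
produce `[[span]][CUI]]`, which the extraction pattern cannot match while
the CUI remains in the text.  Token shuffling and substitution operate only
on inter-marker segments.  Because corruption touches only markers and
non-marker tokens, every preservation failure in a corrupted corpus is
injected and logged — the injection log is exact ground truth, and the QC
report's counts must (and do, in the tests) equal it exactly.

What passing these tests shows: the embedding grammar, extraction pattern,
offset arithmetic and QC attribution are exact on any text obeying the
marker grammar.  What it does not show: real translators produce fluent
reorderings, partial marker translations, bracket styles beyond the one
injected mangle, and language-specific tokenization effects; synthetic text
has none of these, and clinical plausibility is out of scope.  Results on
real corpora and commercial services therefore need their own QC run —
which is precisely what the preservation report is for.

## Numerical and reproducibility notes

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds: generator and corruption configs carry seeds, `split_corpus` takes
  one, replicate experiments derive per-replicate seeds by offsetting the
  config seeds.  Identical config + seed ⇒ bitwise-identical output.
- `split_corpus` rounds the train size to the nearest integer, ties up —
  the rounding rule must be fixed for determinism.  Splitting is
  unstratified uniform.
- Agreement SD is the sample standard deviation (ddof = 1), defined as 0
  for a single document.
- Medians in corpus characteristics are over per-document values;
  documents without annotations count as zero.
- The CLI writes a JSON run manifest (command, options, version, timestamp)
  next to every output for auditability.

## Known limitations

- One marker grammar (double square brackets); SGML/XML-style or
  curly/angle-bracket embeddings are not implemented.
- Overlapping and discontinuous annotations cannot pass through the
  pipeline (rejected or pre-filtered; discontinuous brat spans are rejected
  at read time).
- The residual-CUI count is a per-document proxy: it cannot say *which*
  missing annotation a given residual CUI belonged to, only how many
  formatting failures occurred.
- The toy dictionary extractor is a longest-match scanner intended to
  exercise the evaluator end-to-end, not a concept-extraction baseline.
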