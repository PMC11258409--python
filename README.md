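# cuitrans

Annotation-preserving machine translation of concept-annotated corpora.

## The problem

Clinical and biomedical NLP tools that extract UMLS concepts (named entity
recognition plus linking to a Concept Unique Identifier, CUI) need annotated
corpora for validation — and almost all such corpora are English.  Simply
machine-translating an annotated corpus destroys its value: translation
reorders and rewords the text, so the character offsets of every standoff
annotation become meaningless.

`cuitrans` implements a three-step method that carries the annotations
*through* the translation instead of realigning them afterwards:

1. **Embed** — each annotated span is wrapped in place in an inline marker
   carrying its CUI: `[[span][CUI]]`.
2. **Translate** — the marker-embedded text is sent through any translation
   backend (a document-translation API, a chat LLM with a zero-shot prompt,
   or a mock translator), which translates the span text inside the markers
   along with the rest of the sentence.
3. **Extract** — markers are located in the translated text with the pattern
   `\[\[([^\]\[]*)\]\[(C[0-9]*)\]\]`, the bracket syntax and CUI are
   removed, and each span becomes a standoff annotation with offsets
   recomputed against the cleaned text.

For the sentence `Temporary kidney enlargement in the newborn infant` with
annotations `C0542518: kidney enlargement [10–28]` and `C0021289: newborn
infant [36–50]`:

```
embed      Temporary [[kidney enlargement][C0542518]] in the [[newborn infant][C0021289]]
translate  Tijdelijke [[niervergroting][C0542518]] bij de [[pasgeboren baby][C0021289]]
extract    Tijdelijke niervergroting bij de pasgeboren baby
           C0542518: niervergroting [11–25]   C0021289: pasgeboren baby [33–48]
```

Translators fail in two distinct ways, and the package quantifies both:
a **formatting error** mangles a marker's brackets so the extraction
pattern cannot match and the CUI string is left behind in the text (a
*residual CUI*); **annotation loss** drops the marker entirely while
keeping the sentence intact, leaving no trace.  The preservation-QC report
partitions missing annotations into these two mechanisms per document.

Also included:

- readers/writers for the standardized tabular corpus format (TSV documents
  + annotations tables), PubTator, and brat standoff; seeded train/test
  splitting;
- document-level **BLEU** and **chrF** with pairwise corpus agreement
  summaries (mean ± SD);
- strict-span concept-extraction evaluation (a prediction is correct only
  when CUI *and* exact offsets match; precision/recall/F1 with the 0/0 → 0
  convention), per-corpus mean-centering, and Bonferroni-adjusted Wilcoxon
  group comparisons;
- a synthetic corpus generator and corrupting pseudo-translators with
  *logged* injection ground truth, so every pipeline stage is testable
  without any external data or service.

## Worked example

```python
import cuitrans as ct

doc = ct.Document("d1", "Temporary kidney enlargement in the newborn infant")
anns = [
    ct.Annotation("d1", "C0542518", 10, 28, "kidney enlargement"),
    ct.Annotation("d1", "C0021289", 36, 50, "newborn infant"),
]
emb = ct.embed_annotations(doc, anns)
print(emb.embedded_text)

dutch = "Tijdelijke [[niervergroting][C0542518]] bij de [[pasgeboren baby][C0021289]]"
res = ct.extract_annotations(dutch, "d1")
print(res.clean_text)
for a in res.annotations:
    print(a.cui, a.span_text, [a.span_start, a.span_end])
```

prints

```
Temporary [[kidney enlargement][C0542518]] in the [[newborn infant][C0021289]]
Tijdelijke niervergroting bij de pasgeboren baby
C0542518 niervergroting [11, 25]
C0021289 pasgeboren baby [33, 48]
```

i.e. the annotations survive translation with their offsets recomputed into
the Dutch sentence, and removing the marker syntax recovers the clean text
exactly.

A full synthetic experiment — generate a corpus, corrupt it at known rates,
and check that the QC report recovers the injected error counts exactly:

```bash
cuitrans simulate --seeds 5 --seed 1 --out recovery.tsv
# -> "5 replicates, all exact: True"
```

The CLI exposes the whole workflow: `convert`, `split`, `translate`, `qc`,
`agreement`, `evaluate`, `simulate` (see `cuitrans --help`).

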