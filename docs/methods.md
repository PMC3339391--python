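# Methods

This note documents the models and procedures implemented in `trialminer`,
the parameters that matter, the choices made where the design was open, and
what the synthetic fixtures do and do not establish about real registry data.

## Protocol model and normalization

A protocol record carries four text sections (title, brief summary, detailed
description, eligibility criteria) and the structured fields behind seven
metadata facets. Text is NFC-normalized with CRLF→LF; title/summary/
description lines are trimmed, while the eligibility section only has
trailing whitespace and the *common* leading indent removed, because bullet
nesting downstream is read from relative indentation. Absent XML elements
map to empty strings or empty sets — records in the wild are sparse
(observational studies carry no interventions) and that must never be an
error. The reference XML dialect is the legacy ClinicalTrials.gov element
vocabulary; unknown elements are skipped so newer schema revisions degrade
gracefully rather than fail.

## C-Value term extraction

Candidates are contiguous within-sentence token spans of length ≥ 2 whose
part-of-speech string fully matches the noun-phrase filter
`(ADJ|NOUN)+ NOUN`. Every pattern-satisfying sub-span of a match is emitted
too: nestedness is only observable if fragments are themselves candidates.
Frequencies f(α) count *all* occurrences of the token sequence, including
those inside longer candidates; this guarantees N(α) ≥ 0 and matches the
original formulation of the measure. Scoring proceeds longest-first, retains
candidates with C-value strictly greater than 1, and orders the output by
C-value descending, then token length descending, then lexicographically —
a total order, so identical input yields identical ranked output.

The shipped tagger is a deterministic closed-class-lexicon + suffix-rule
heuristic over the coarse tagset {ADJ, NOUN, VERB, OTHER}, with a deliberate
noun bias for unknown words (out-of-lexicon biomedical vocabulary is mostly
nominal, and the downstream filter only passes noun-phrase shapes). The
adjective suffix list is intentionally narrow: broad endings such as
*-ent*/*-ant*/*-ory* mis-tag frequent clinical nouns (consent, patient,
treatment, history) and silently destroy noun-phrase candidates. The tagger
is a contract — any callable mapping a token list to a tag list can replace
it, e.g. a wrapper around a trained biomedical tagger.

Candidate surfaces are lowercased but not lemmatized; term frequencies are
pooled corpus-wide before facet attribution (the per-protocol alternative
would change scores for corpora with very uneven section lengths).

## Eligibility sections

Three layouts are recognized. A section with bullet/numbered lines and an
`inclusion criteria` / `exclusion criteria` header (case-insensitive,
optional colon) is an inclusion/exclusion list; bullets under other
colon-terminated all-caps or title-case headers form an aspect list, whose
items are all treated as inclusive; anything else — including the empty
section — is free text. Free-text sections yield no criterion items by
contract: reliable criterion extraction from free prose would need deep
parsing and domain rules, so there the pipeline falls back to whole-section
concept tagging only.

Bullet markers are `-`, `*`, `•`, `1.`, `1)`, `(1)`; the indent level is the
leading-whitespace width in steps of two spaces (tabs count as two). Only
leaf bullets become criteria: a bullet followed by a more-indented bullet is
grouping context ("… including:") and is not emitted. The alternative —
prepending parent text to each leaf — was considered and rejected as it
manufactures sentences that never occur in the record. Segmentation is
invariant under re-indenting the whole section by a constant offset.

Concept tagging is greedy longest-match, case-insensitive, token-boundary
respecting and non-overlapping, over a TSV lexicon
(`surface, concept_id, preferred_name, snomed_flag`). The lexicon is the
user's stand-in for licensed terminology content; the SNOMED flag models a
clinical-terminology subset, so `SNOMEDCT_concept ⊆ concept` holds by
construction. The section-level facet is the union of whole-section tags and
criterion-level tags, which keeps the subset invariants
(`inclusion ∪ exclusion ⊆ concept`) robust against rare cases where greedy
matching across line boundaries differs from per-item matching.

## Criteria recommendation

Concept frequencies are counted within the eligibility sections of the
selected protocols only. Each pooled criterion scores the arithmetic mean of
its contained concepts' frequencies — the mean rather than the sum so long
criteria are not favoured; criteria containing no known concept score 0 but
stay in the list (the user should still see them). Duplicates are detected
by case-folded, whitespace-collapsed string equality — fuzzy matching would
be an unstated extension — and the first occurrence is kept. Ties break by
score, then number of contained concepts, then text. Replicating the whole
selection k times multiplies every score by k and never reorders, which the
tests assert. Recommended criteria keep their source polarity as metadata;
the user is free to re-assign it when composing the final report.

## UTC clustering

The feature-by-object matrix has one column per document and one per term,
where a term's pseudo-document consists of its own tokens. Weights are raw
term frequency × smoothed idf, `idf = ln((1+N)/(1+df)) + 1`, with idf fitted
on document columns only and reused for term columns (fitting it on all
columns would let the term list itself shift feature weights); an unsmoothed
variant `ln(N/df)` is available for analyses that need ubiquitous features
to vanish exactly. No column normalization is applied to the matrix —
downstream comparisons are cosines, which are scale-free.

The co-embedding is a truncated SVD: with X = U S Vᵀ, object j maps to the
first k entries of S Vᵀ's column j. At k = rank(X) this is an isometry on
column cosines (U has orthonormal columns), which the tests verify to 1e-9.
Sign convention: each left singular vector is flipped so its
largest-magnitude entry is positive, making the embedding reproducible
across linear-algebra backends. The factorization is deliberately behind the
`co_embed` interface; the contract (common space, cosine preservation at
full rank, concurrent clusterability) is what the rest of the pipeline and
the tests rely on, so other collective factorizations can be swapped in.

Clustering is k-means over *all* objects — documents and terms together —
via scikit-learn's k-means++ with a fixed seed, 50 restarts and 300 max
iterations (empty clusters are re-assigned by scikit-learn's internal
mechanism). The embedded vectors are L2-normalized before clustering
(spherical k-means): document and term columns differ enormously in norm
while carrying meaning only in their direction, and without normalization
every term collapses into a single near-origin cluster instead of joining
its topic. Defaults: embedding dimension min(50, rank−1) and 10 clusters,
both configurable; 10 matches the group counts a result-browsing interface
typically shows.

Each term t in cluster c scores Σ_{d∈c} cos(e[t], e[d]); the top term labels
the cluster (lexicographic tie-break). A cluster that attracted no term
falls back to the highest-total-tf-idf unigram of its documents.

### Quality metrics

Definitions used here (terms are excluded from all three):

- **purity** = (1/N) Σ_c max_class |c ∩ class|;
- **pairwise cluster contamination** = fraction of same-cluster document
  pairs whose true classes differ (0 when no pairs exist);
- **within-cluster similarity** = mean pairwise cosine of same-cluster
  documents in tf-idf space (0 when no pairs exist).

Purity is standard; the other two names appear in the literature without
printed formulas, so the definitions above are this package's own and
published values computed under unknown definitions are not comparison
targets.

## Synthetic corpus generator

`generate_corpus` emulates the statistical skeleton the pipeline needs:
topical clusters with disjoint (or noise-contaminated) vocabularies,
repeated two-word noun phrases for the term extractor to find, function-word
connectors so the noun-phrase filter does not span unrelated content words,
Table-style inclusion/exclusion eligibility sections embedding known concept
surface forms, and rotating facet values. Defaults used throughout the tests
and the acceptance script: 3 clusters × 20 documents, 12-word cluster
vocabularies, ~120 body tokens per document, noise rate 0 for the recovery
fixture — small enough for the whole suite to run in seconds yet large
enough that cluster recovery is non-trivial. It is a pure function of its
spec, so identical seeds give byte-identical corpora.

What it does **not** emulate: real registry prose (abbreviations, units,
misspellings, mixed layouts within one section), realistic tag ambiguity,
polysemous concept surfaces, or power-law vocabulary growth. Passing the
recovery tests therefore demonstrates the pipeline's mechanics — correct
scores, correct algebra, correct concurrent clustering — not clustering
accuracy on live registry content, which depends on corpus scale and
terminology coverage unavailable offline.

## Numerical and degenerate-input conventions

- Zero-norm vectors have cosine 0 with everything (affects empty documents
  and terms whose tokens all lack document support).
- `co_embed` rejects k outside [1, rank]; numerical rank uses an
  eps-scaled singular-value threshold.
- Empty eligibility sections are legal everywhere and simply invisible to
  eligibility-derived facets; an empty selection for the recommender is a
  validation error (scoring over nothing is meaningless), while a selection
  with no extractable criteria returns an empty list.
- Queries are conjunctive (AND) with results ordered by total query-token
  frequency then id; the empty query returns every document. Result
  ordering is this package's choice — a relevance-ranked engine would order
  differently, and nothing downstream depends on the order.
- All randomness (corpus generation, k-means) is seed-controlled; every
  CLI artifact is written with sorted keys/rows so repeated runs are
  byte-identical.

## Known limitations

- The default tagger is a heuristic; precision of the extracted terms on
  real text is bounded by its tagging quality. It is replaceable via the
  tagger contract.
- Dictionary concept tagging has no disambiguation: a surface form maps to
  exactly one concept.
- The index is fully in-memory and single-process; it targets corpora that
  fit in RAM, not registry-scale deployments.
- Aspect-list polarity is a blanket "inclusive" assignment; sections mixing
  headers with free-text paragraphs are classified by the first matching
  rule.
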