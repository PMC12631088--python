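# Methods

This note documents the models and procedures `phenospan` implements, the
tunable parameters and their defaults, the numerical and design choices
that were genuinely open, and what the synthetic test regime does and does
not demonstrate.

## Annotation model

A corpus is a list of observations, each a short clinical text with zero or
more labeled mentions. A mention is 1–3 character-offset fragments, 0-based
and half-open `[start, end)`, sorted, non-overlapping, and separated by at
least one character (adjacent fragments would denote a contiguous span and
must be merged). Labels are `KEYF` (key finding, normalized to an HPO
identifier `HP:` + 7 digits) and `NORMF` (normal finding, never
normalized). Mentions may overlap each other: coordination ellipsis
produces shared heads ("thumbs are" shared by "thumbs are long" and
"thumbs are broad"). The on-disk format is 5 tab-separated columns
(observation id, text, HPO id, polarity, spans); polarity `X` marks normal
findings and `NA` key findings, and discontinuous spans are comma-separated
ranges (`17-27,37-42`). The reader accepts the `N/A` spelling and spaces
around the comma; it writes back the canonical forms. A lenient reading
mode skips invalid rows with their row numbers (real corpora of this kind
contain occasional offset inconsistencies); strict mode, the default,
fails fast.

## Seq2seq serialization

Targets are `"<LABEL>: <surface>"` segments joined by `"; "`, with a
mention's surface being its fragment substrings joined by single spaces —
no extra markup distinguishes discontinuous mentions. Deterministic segment
ordering matters only for reproducible training targets; the rule is KEYF
before NORMF, then the tuple of fragment start offsets, then the surface.
Decoding is defensive: segments are split on `;`, the label is taken from
the first `KEYF:`/`NORMF:` prefix only (so surfaces containing colons
survive), duplicates collapse, and anything unparseable is skipped and
counted through a warnings channel. A surface containing the separator
cannot round-trip; the encoder logs it (the synthetic generator never
produces one, real data could).

## Grounding

Generated surfaces carry no offsets. Grounding searches, in order:

1. the leftmost *contiguous* occurrence of the surface (one fragment);
2. token-run placements: the surface's whitespace tokens are partitioned
   into at most `max_fragments` (default 3, matching the 2–3 constituent
   parts observed in such corpora) contiguous runs, each matching a run of
   text tokens, runs strictly left-to-right with at least one text token
   between them. Among feasible placements the minimum of
   (fragment count, fragment start offsets lexicographically) is returned,
   preferring contiguous readings and then leftmost ones.

Matching is case-sensitive with a full case-insensitive fallback pass, and
a token whose exact comparison fails is retried with edge punctuation
stripped (fragments stay tight to the stripped core, so "hooding" grounds
inside "hooding."). Punctuation stripping applies per token; interior
tokens of a run are matched the same way as edge tokens. An infeasible
surface yields an *ungrounded* value rather than an exception — callers
drop it from span output but must count it, since it silently costs
precision. The implementation is exercised against an exhaustive oracle
that enumerates every legal placement on randomized texts of ≤12 tokens.

## NER backends

The backend contract is one deterministic function from observation text
to a target string. The shipped `DictionaryStubBackend` scans the text
left-to-right for longest case-insensitive dictionary-surface matches on
token boundaries and emits them as `KEYF` segments, flipping to `NORMF`
when the match starts with or is immediately preceded by a negation cue
(defaults: "no", "normal", "intact"; the emitted surface excludes a
preceding cue). It is a real, fully specified backend for desk-scale
pipeline runs, not a model: it cannot produce discontinuous surfaces, and
its negation heuristic is one-token-deep. Trained seq2seq models are
expected to satisfy the same contract.

LoRA arithmetic is included as standalone algebra for merging low-rank
adapter weights: `ΔW = B·A` with `B ∈ R^{d×r}`, `A ∈ R^{r×k}`,
`r ≤ min(d,k)`, merged as `W = W₀ + (α/r)·B·A`. The scaling constant α and
rank r are hyperparameters of the adapted model; the merge is linear in α
and the merged delta has matrix rank at most r, both property-tested.

## Normalization

Retrieve-then-rerank over an ontology dictionary:

* **Dictionary.** Two-column (term, id) rows; the first surface per id is
  the preferred term, later ones synonyms. `augment_dictionary` adds
  training-corpus KEYF surfaces as synonyms of their annotated ids (a
  surface annotated with two ids yields two synonym rows; normal findings
  are ignored). Augmentation never mutates or removes existing entries.
* **Candidate generation.** Every entry — synonyms as separate rows — is
  embedded once; a query surface is scored against all rows by cosine
  similarity and the top `k` (default 30) are kept. Ties break by surface
  then id, so rankings are reproducible; scores are clipped to [−1, 1]
  against floating-point spill. Duplicate ids may appear in a candidate
  list: collapsing them would silently change the meaning of `k`.
* **Reranking.** Each (mention, candidate term) pair is rescored
  independently and the list re-sorted under the same tie rule; the top
  candidate's id is the answer.

The reference encoder is a hashing character-3-gram embedder: case-fold,
pad with `#` boundary markers, hash each 3-gram (CRC-32) into `dim`
buckets (default 1024; a power of two ≥1024 is enforced), accumulate term
frequencies, L2-normalize. Identical strings embed identically, so an
exact-surface query always retrieves its own entry at rank 1 with score
1.0. The reference reranker is the Dice coefficient over case-folded word
sets. Both are deterministic and dependency-free stand-ins that preserve
the architecture; trained biencoders and cross-encoders plug in through
the `EncoderContract`/`RerankerContract` protocols. With the Dice
reranker, two surfaces with identical word *sets* tie and resolve
lexicographically — the synthetic dictionary generator therefore never
emits two word-order permutations of the same surface.

## Evaluation

Precision `TP/(TP+FP)`, recall `TP/(TP+FN)`, F1 the harmonic mean
`2PR/(P+R)`; degenerate denominators score 0. Matching regimes:

* **exact** — fragment offset tuples identical;
* **partial** — at least one whole token (maximal non-whitespace run,
  fully covered by a fragment) shared; sharing characters but no whole
  token does not count;
* **normalization-only** — per-observation multiset intersection of KEYF
  HPO ids, spans ignored; mentions lacking an id are unmatchable but stay
  in the denominators;
* **combined** — span match under the chosen mode *and* equal ids (two
  absent ids compare equal, so unnormalized NORMF predictions can match
  unnormalized NORMF golds);
* **disjoint-only** — gold restricted to ≥2-fragment mentions; every
  prediction may match a retained gold, but unmatched predictions count
  as false positives only if themselves discontinuous;
* **class-wise** — both sides restricted to one label first.

Matching is one-to-one and greedy by descending shared-character count,
ties by gold offset order. The official scorer's assignment policy for
this task is not published; greedy-by-overlap is deterministic and makes
exact-mode true positives provably a subset of partial-mode ones, which
the suite asserts on seeded perturbation fixtures. Counts are verified
against a from-scratch naive matcher on 200 seeded corpora.

Overlap-structure categorization of a discontinuous mention against its
siblings: no shared token → no overlap; one consecutive shared region
contained in the first/last fragment → left/right overlap; several
regions, a region confined to a middle fragment, or ≥2 sharing siblings →
multiple overlap. Token granularity is one consistent reading of the
category names; fragment granularity would differ only for partial-token
sharing, which the corpus format cannot express.

## Synthetic data

The generator emulates the structural regime the pipeline assumes, not
clinical language. Observations are `SECTION: …` texts over a body-part /
quality vocabulary chosen so no generator word is a substring of another;
within one observation no mention surface or surface word repeats, so
every gold surface has a unique feasible grounding. Mentions per
observation: 1 + Bernoulli(0.5) (≈1.5 on average, matching ~2562 entities
over 1716 observations). Each mention draws discontinuity
(default 369/2562 ≈ 14.4%) and polarity (329/2562 ≈ 12.8%) as independent
Bernoullis, so realized rates are exactly binomial in the mention count —
the calibration tests use exact central 99% binomial intervals. Structures:

* continuous mention, optionally preceded by a filler adverb; normal
  findings carry a leading "no" cue inside the span;
* interrupted ("no overlap") discontinuous mention: surface words
  separated by 1–2 filler tokens; 3-part mentions use 3-word surfaces
  (2-part:3-part target 358:11);
* shared-head pairs from coordination: left overlap ("thumb broad and
  elongated"), right overlap ("wrist and ankle broad"), multiple overlap
  ("broad thumb and hallux crease") — each realized together with its
  sibling mention.

Pair structures need a second mention in the observation, so the overlap
mix (defaults 26/42/20/12% for no/left/right/multiple, from the observed
category counts of such corpora) is honored only approximately, while the
discontinuity and polarity rates stay exact. Normal findings carry no gold
HPO id (they are never normalized); key-finding surfaces are always
dictionary surfaces so exact-surface normalization can recover their ids.

`perturb_predictions` derives controlled imperfect predictions: per
mention, independent deletion, one-token fragment-boundary shift, and id
corruption. Under pure deletion at rate q, exact recall is a
Binomial(n, 1−q) fraction, which the calibration tests assert.

What passing these tests shows: the codec, grounding search, retrieval
ranking, metric definitions and pipeline plumbing are correct on data with
exactly the advertised structures. What they do not show: performance on
real clinical text — paraphrase, morphological variation, annotation
noise, substring-nested vocabulary and genuinely ambiguous placements are
all absent from the synthetic regime by construction.

## Problem sizes and defaults

Test-suite and acceptance-script sizes were chosen to exercise each
property at statistical scale while keeping a full run in seconds: toy
dictionaries of 120–200 ids, corpora of 60–2000 observations (the binomial
calibration uses 2000 observations ≈ 3000 mentions), 200 seeded
perturbation corpora for oracle equivalence, and 120–150 randomized texts
for the exhaustive grounding oracle.

## Known limitations

* The grounding objective (fewest fragments, then leftmost) is a
  deterministic formalization; where a real corpus prefers a non-leftmost
  gold placement of an ambiguous surface, grounding picks the leftmost.
* The stub backend cannot emit discontinuous surfaces; end-to-end
  exact-recovery smoke runs therefore use continuous-only corpora, and
  discontinuous grounding is exercised directly on gold surfaces instead.
* `evaluate_spans` matches across labels (label identity is not required
  for a span match); use `classwise` for label-faithful span scores.
* The reference encoder measures lexical overlap only; it is not a
  semantic model and will mis-rank true synonyms with disjoint wording,
  exactly the failure mode trained biencoders exist to fix.
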